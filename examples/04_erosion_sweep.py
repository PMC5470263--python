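"""How concerted evolution erodes the footprints of duplication history.

Families are simulated across a sweep of gene-conversion rates and fully
re-analyzed; as the rate grows, signature retention and diagnostic-site
recall fall while paralogs converge within species.
"""

from duptrace.pipeline import RunConfig, run_recovery_experiment
from duptrace.simulate import SimConfig

cfg = RunConfig(sim=SimConfig(), conv_rates=(0.0, 0.2, 1.0, 5.0), seed=42)
reps, summary = run_recovery_experiment(cfg, n_reps=10)

cols = ["conv_rate", "retention_median", "lineage_accuracy_median",
        "precision_median", "recall_median", "monophyly_fraction"]
print(summary[cols].to_string(index=False))
# retention_median: surviving diagnostic columns per species (of 16);
# recall_median: fraction of true sites the pipeline still recovers;
# monophyly_fraction: replicates whose NJ tree keeps the two lineages as
# reciprocally monophyletic clades. All fall as conv_rate rises.
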