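# duptrace

**Tracing multigene-family duplication history under erosion by concerted
evolution.**

Ancient gene duplications leave two kinds of footprints in a multigene
family sampled across many species: *diagnostic sites* — alignment columns
where the two paralog lineages carry different fixed variants — and a
phylogenetic pattern in which each species' copies fall into two deep,
lineage-wise clusters. Concerted evolution works against both: intergenic
gene conversion copies short tracts between a species' paralogs,
intermingling the lineage signatures and pulling copies together until the
tree clusters by species instead — a pattern that can mimic repeated gene
loss under birth–death evolution. The motivating case is the avian MHC
class IIB family, where two lineages born before the radiation of extant
birds survive in some orders and are homogenized beyond easy recognition in
others.

`duptrace` is a library (plus a thin CLI) for people who study this
process. It provides:

- **Signature screening** (`duptrace.signatures`) — classify every sequence
  against a table of diagnostic columns with lineage-A/B variants: per-column
  profiles, lineage calls with a minority-fraction rule for intermingled
  sequences, most-lineage-like representatives per species or order, and
  *signature retention* — the number of diagnostic columns at which a
  group's most-A-like and most-B-like sequences still differ (`0` =
  fully homogenized, signature length = fully retained).
- **Local-phylogeny segmentation** (`duptrace.segmentation`) — partition
  alignment columns into classes with a common local signal ("cacti"),
  each a pairwise-distance pattern over all sequences plus its column set.
  Columns are assigned by a Viterbi pass over per-column emission costs
  with a switch penalty; new cacti are proposed by deterministic
  change-point splits and kept only when the total cost drops.
- **The duplication-history statistic** (`duptrace.duplication`) — for each
  cactus, the cross-species mean of the distance between every species'
  *two most distant* sequences (the max-pair, not the mean-pair, so species
  with many sequences do not bias the statistic), normalized across cacti.
  Cacti scoring near the top reflect duplication history; their columns are
  the recovered diagnostic sites.
- **Distances and trees** (`duptrace.distances`) — uncorrected p-distances
  with pairwise deletion, deterministic neighbor joining, monophyly checks.
- **A gene-conversion simulator** (`duptrace.simulate`) — a two-lineage
  family evolving along a random ultrametric species tree with
  Jukes–Cantor substitutions, Poisson gene-conversion events with
  geometric tract lengths, optional lineage dropout, and an exact event
  log, so every analysis can be validated against known ground truth.

## The statistic

For cactus $c$ with normalized distance matrix $D_c$ and species $s$ with
sequence set $S_s$ (only species with $|S_s|\ge 2$ count):

$$\mathrm{raw}(c) = \frac{1}{|\mathcal S|}\sum_{s\in\mathcal S}\ \max_{i,j\in S_s} D_c(i,j),
\qquad \mathrm{norm}(c) = \frac{\mathrm{raw}(c)}{\max_{c'} \mathrm{raw}(c')}$$

Columns that trace the duplication split each species' paralogs deeply
(max-pair distance near the matrix maximum), columns under concerted
evolution keep conspecific copies close; a cactus is labeled *duplication
history* when $\mathrm{norm}(c)$ reaches the top of the scale (default
cutoff 0.9, configurable; `top_k` labeling is also available).

## Worked example

`examples/03_discover_sites.py` simulates a conversion-free family
(20 species, 300 columns, a 16-column diagnostic block) and runs the full
discovery pipeline:

```text
cacti: 2
  cactus 0: raw 0.641  normalized 0.641  -> concerted
  cactus 1: raw 1.000  normalized 1.000  -> duplication
recovered sites: [281, 282, ..., 296]
true sites:      [281, 282, ..., 296]
precision 1.00, recall 1.00
```

Cactus 1 captures the diagnostic block — under it every species' two copies
sit at maximal distance, so it takes the top score and its 16 columns are
recovered exactly. `examples/04_erosion_sweep.py` repeats this across a
gene-conversion-rate sweep (10 replicates per rate):

```text
 conv_rate  retention_median  lineage_accuracy_median  precision_median  recall_median  monophyly_fraction
       0.0              16.0                   1.0000          1.000000            1.0                 1.0
       0.2              16.0                   0.9750          1.000000            1.0                 0.6
       1.0              16.0                   0.9375          0.970588            1.0                 0.3
       5.0               0.0                   0.5625          0.000000            0.0                 0.0
```

As the conversion rate rises, signature retention collapses from 16 to 0,
diagnostic-site recall goes to zero, and the two lineages stop being
reciprocally monophyletic — the erosion of duplication history, measured.

The other examples show the simulator's event log and the per-sequence
intermingling profiles (e.g. `sp01_B` carrying `AAAAABBBBBBBBBBB` after an
ancestral conversion tract).

## Command line

```bash
duptrace simulate  --config cfg.yaml --out-prefix fam       # fam.fasta, fam.groups.tsv, ...
duptrace screen    --aln fam.fasta --groups fam.groups.tsv --signature fam.signature.tsv --out screen.tsv
duptrace partition --aln fam.fasta --iterations 5 --out seg.json
duptrace discover  --aln fam.fasta --groups fam.groups.tsv --out sites.tsv
duptrace experiment --conv-rates 0,0.2,1,5 --n-reps 20 --seed 1 --out-dir exp/
```

Inputs are plain FASTA (alignment), TSV (`seq_id  species  group` map;
`column  variantA  variantB` signature table, 1-based columns), newick, and
YAML configs; all randomness flows from the config seed.

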