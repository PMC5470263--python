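# Methods

## The problem and the model

A multigene family whose members duplicated long before the sampled
species radiated carries two superimposed histories. At most columns,
substitutions record the species phylogeny; at a minority of *diagnostic*
columns, the two paralog lineages fixed different variants shortly after
the duplication, so these columns record the duplication itself. Intergenic
gene conversion between a species' paralogs (concerted evolution) copies
tracts from one copy onto the other, erasing the diagnostic divergence
within that species and — given enough time and rate — re-clustering trees
by species. `duptrace` implements three analysis stages (signature screen,
local-phylogeny segmentation, duplication-history statistic) and a
simulator that generates families with known truth so the stages can be
validated end to end.

## Simulator

One ancestral sequence is duplicated at the root of a random ultrametric
species tree into lineages A and B. The tree is built by random pairwise
joins with exponential waiting times and rescaled to `tree_height`
(a Yule-like shape; leaves `sp01..spNN`). Down every branch, each copy
accumulates `Poisson(sub_rate * L * seq_len)` Jukes–Cantor substitutions
(uniform choice among the three other bases), then each copy draws
`Poisson(conv_rate * L)` gene-conversion events whose donor→recipient
direction is uniform, so a branch of length `L` carries
`Poisson(2 * conv_rate * L)` events in total. Each event copies a
geometric tract (mean `tract_mean`, uniform start, clipped at the sequence
end) from the conspecific paralog. At the tips each species independently
loses one copy (A or B with equal probability) with probability
`dropout_p`.

Parameters, units and defaults:

| parameter | meaning | default |
|---|---|---|
| `n_species` | extant species | 20 |
| `seq_len` | alignment columns | 300 |
| `k_diag` | diagnostic columns | 16 |
| `sub_rate` | substitutions / site / unit branch length | 0.05 |
| `conv_rate` | conversion events / gene copy / unit branch length | 0 |
| `tract_mean` | mean conversion tract (columns, geometric) | 50 |
| `dropout_p` | probability a species loses one copy | 0 |
| `tree_height` | root-to-tip depth (time units) | 1 |
| `diag_span` | window width holding the diagnostic columns | `k_diag` |

With `tree_height = 1` and `sub_rate = 0.05`, root-to-tip divergence is
~5% per copy and cross-lineage pairs sit near 10% — the order of magnitude
seen in cross-species nuclear gene-family alignments. No quantitative
conversion rate or tract-length estimates exist for the motivating system;
`tract_mean = 50` and the sweep `conv_rate ∈ {0, 0.2, 1, 5}` are this
package's own choices, spanning "no erosion" to "retention destroyed
within the tree's depth".

Diagnostic columns are placed as one contiguous block at a random position
(`diag_span = k_diag`), mirroring signatures concentrated in a short
stretch of a single exon; setting `diag_span` larger scatters them inside
a window. By default substitutions at diagnostic columns are rejected and
resampled, so gene conversion is the *only* force eroding the signature
and erosion curves are attributable to it alone;
`erode_by_substitution=True` lifts the protection. Founder lineage-A
variants equal the ancestral base; lineage-B variants are drawn uniformly
from the other three.

All randomness flows through one numpy `Generator` in a documented order
(tree first, then founder, then pre-order over branches with substitutions
before conversions and copy A before copy B, dropout last in leaf order),
so a seed fixes every output byte. Every substitution and conversion is
logged; replaying the log over the stored tree reproduces the final
alignment exactly, which the test suite asserts.

What the simulator does *not* model: indels and alignment error, selection
(including the balancing selection typical of peptide-binding exons), rate
heterogeneity across sites or lineages, more than two paralogs, conversion
between non-conspecific copies, and biased gene conversion. Passing tests
therefore show that the pipeline recovers duplication history from
conversion-eroded point-substitution data, not that it is robust to
misalignment or selective convergence.

## Signature screen

A sequence is tallied at each signature column: equal to the lineage-A
variant, to the lineage-B variant, to neither ("other"), or gap/N (gap
columns are excluded from all counts and from retention — a conservative
convention, since how gaps inside a signature should count is not
otherwise defined). The lineage call is A (or B) when that lineage has
more matches *and* the minority fraction `min(nA,nB)/(nA+nB)` is below a
threshold (default 0.25, the package's explicit operationalization of
"about equal proportions"); at or above the threshold, or at an exact tie,
the call is *intermingled*; with no A/B matches at all, *uninformative*.
Per-group representatives maximize the own-lineage count with ties broken
by fewer opposite-lineage matches, then lexicographically smallest id, so
reports are deterministic. Retention is the count of signature columns at
which the most-A-like and most-B-like representatives differ; a
single-sequence group scores 0 by construction.

## Segmentation into cacti

Only variable columns are analyzed (monomorphic columns carry no signal;
they are attached afterwards to the preceding variable column's class, so
optima are unchanged but every column gets a label). Each column is
reduced to its 0/1 pairwise difference pattern over all sequence pairs
(gap pairs are missing and carry no weight). A cactus is fitted as the
centroid (mean pattern) of its columns; the emission cost of a column
under a cactus is the mean squared deviation over non-missing pairs, and a
column path over cacti is scored as total emission plus `switch_penalty`
per state change, minimized exactly by a Viterbi pass (ties resolve to the
smaller state index).

Fitting starts from a single cactus and, for a fixed number of iterations,
proposes one new cactus per iteration: the change point that most reduces
the squared deviation around per-side centroids (both sides at least
`min_segment` columns; missing pairs scored as no difference in this
heuristic), seeds the trial assignment with that split, refines it by
alternating centroid re-estimation with the Viterbi pass until the total
cost stops dropping, and keeps the proposal only if the refined total cost
beats the incumbent. Proposing stops early when no split improves. The
total cost is therefore non-increasing across accepted iterations, and the
whole procedure is deterministic — no RNG anywhere in this module.

Defaults: `min_segment = 10` columns (diagnostic signal spans short
stretches; shorter runs overfit single columns) and `switch_penalty` =
twice the median per-column emission cost of the initial single-cactus fit
(scale-free, so it adapts to divergence level). Degenerate inputs are
rejected with clear errors: fewer than 4 sequences, `min_segment` longer
than the alignment, or no variable columns.

The reported cactus matrix is the max-normalized mean difference matrix of
its assigned columns (entries in [0, 1], so the duplication statistic is
comparable across cacti); internally the fit uses the *unnormalized*
centroids, which are the MSE-optimal representatives. This segmenter is a
deliberately simple functional analog of HMM+SOM local-phylogeny methods —
the SOM stage is replaced by deterministic change-point proposals — and is
validated by breakpoint-recovery experiments (two 100-column blocks
simulated on different 12-taxon topologies; the fitted boundary lands
within ±`min_segment` of the true join in ≥18/20 fixed-seed replicates),
not claimed to reproduce any particular existing implementation or its
parameters.

## Duplication-history statistic

For each cactus, take every species with at least two sequences, find its
two most distant sequences under the cactus matrix (max over conspecific
pairs; reported pair tie-broken lexicographically), average these maxima
across species, and normalize by the maximum across cacti (all zeros stay
zero; normalization is idempotent). Using the most distant pair rather
than all pairs keeps species with many sequences from biasing the mean;
single-sequence species are excluded as they carry no within-species
distance.

Classification: a cactus is labeled *duplication history* when its
normalized score is at least `threshold` (default **0.9**), otherwise
*concerted evolution*; a `top_k` mode labels the k best instead. The
cutoff deliberately sits near the top of the scale: in a family with *no*
homogenization, paralogs are deeply diverged at every column, so even
species-pattern cacti score a substantial fraction (~0.6–0.8) of the top
cactus and a mid-scale cutoff would label nearly everything duplication;
in a heavily homogenized family, concerted cacti fall far below either
way. "Within 10% of the top cactus" separates both regimes. The exact
normalization and cutoff are this package's explicit choices — the
underlying qualitative rule ("high within-species divergence marks
duplication-history cacti") leaves both open. Recovered diagnostic sites
are the union of duplication-labeled cacti's columns, reported 1-based.

## Distances and trees

p-distances are uncorrected proportions with pairwise deletion (columns
with a gap or N in either sequence are excluded per pair); a pair with no
comparable columns gets NaN, which neighbor joining refuses — callers
filter first, since NJ has no principled missing-data handling. NJ follows
the Saitou–Nei Q-criterion with two determinism rules: Q-ties are broken
by the lexicographically smallest label pair (internal nodes carry their
smallest descendant label), and negative branch lengths are clamped to
zero. Monophyly of a leaf subset is evaluated unrooted: true iff some edge
bipartitions the leaves into exactly (subset, complement).

## Recovery experiment and its metrics

`run_recovery_experiment` simulates families across a conversion-rate
sweep and re-analyzes each replicate from scratch: median per-species
signature retention, lineage-call accuracy against truth (intermingled and
uninformative calls count as misses), precision/recall of recovered
diagnostic sites against the true block (precision is NaN when nothing is
recovered and is excluded via nanmedian — it cannot be sensibly scored),
reciprocal monophyly of the two true lineages on the NJ tree, and the
fraction of species whose paralogs are mutually nearest neighbors in
p-distance. A replicate is counted as "paralog-clustered" when more than
half of its two-copy species have mutually-nearest paralog pairs — the
package's aggregation choice for an otherwise qualitative tree-pattern
contrast. Replicate seeds derive from the experiment seed through one
parent generator, so runs are exactly reproducible.

A quantitative note on the clustering regime: with conversion events
covering ~28% of the sequence each (uniform start, geometric tract,
clipping), the per-site homogenization rate at `conv_rate = 5` is ~2.8 per
unit branch length, so the expected time since a site was last homogenized
(~0.35) is comparable to the pendant branch lengths of a 20-species
Yule-like tree of height 1 (~0.3). Conspecific paralog distance then
averages *above* the nearest-ortholog distance, and most species do not
show mutually-nearest paralogs until far higher rates (measured: ~32% of
species at `conv_rate = 5`, ~66% at 20, ~86% at 50). Tip-level paralog
clustering is therefore a high-rate phenomenon in this model, while
signature retention and site recall already collapse at `conv_rate = 5`.

## Problem sizes used in tests and the acceptance script

The default study conditions (20 species × 2 copies, 300 columns, 16
diagnostic sites, ~10% cross-lineage divergence) run end to end in well
under a second per replicate; the test suite uses 10–20 replicates per
property and the sweep uses 20 per rate, sizes chosen as the smallest at
which the medians and pass-rates are stable across seed sets. The
breakpoint experiment uses 12 taxa and 100+100 columns at `sub_rate 0.15`
(mean pairwise divergence ~0.2, typical of cross-species gene-family
alignments).

## Known limitations

- The segmenter proposes contiguous segments; diagnostic columns scattered
  thinly across the whole alignment (rather than concentrated in blocks)
  will not be isolated into their own cactus.
- The statistic needs several species with both copies retained; under
  heavy dropout it loses power (and is undefined with no two-copy species).
- With no homogenization anywhere, *every* column genuinely reflects
  duplication history; the near-top cutoff then reports only the strongest
  (diagnostic-block) cacti, which is the useful behavior but means
  "concerted" labels in such data do not imply homogenization.
- p-distances saturate for deep divergences; no model correction is
  offered, matching the uncorrected-distance convention of the screening
  context rather than deep-phylogeny use.
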