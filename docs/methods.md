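# Methods

`rpmeta` implements a complete two-group transcriptomics comparison
pipeline of the kind used to profile F508del-CFTR airway epithelium
against healthy controls: Rank Products differential-expression calling
with a permutation null, construction and harmonization of directional
gene lists, cross-study concordance/inversion meta-analysis ending in an
intersection "molecular signature", generic enrichment statistics, and
qPCR relative-quantification validation. A synthetic multi-study
generator with known ground truth makes every stage testable without any
data download.

## Rank Products

For a study with `n_case` case and `n_control` control samples on a log2
expression matrix of N probes, all k = n_case x n_control pairwise
case/control log-ratios are formed. Within each pairwise comparison the
probes are ranked (rank 1 = most up-regulated for the "up" analysis, most
down-regulated for "down"; ties get average ranks), and the Rank Product
of a probe is the geometric mean of its k ranks, computed in log space to
avoid overflow. Consistently top-ranked probes get RP near 1. The
all-pairs scheme is used rather than a single group-mean ratio because it
is the formulation that gives the statistic its robustness at very small
replicate numbers (the motivating studies are 5 vs 5).

Significance comes from B random-gene-order experiments (default
B = 1000). For each observed RP_g,

* E_g = #{null RP <= RP_g} / B — expected false positives at that RP,
* p_g = E_g / N, floored at 1/(B·N) (a permutation p of exactly 0 is an
  artifact of finite B),
* pfp_g = E_g / rank_g — the percentage of false prediction, RP's FDR
  analogue, where rank_g is the probe's position in the RP ordering.

### The null: two schemes

The idealised null draws the k rank columns as independent uniform
permutations of 1..N (`permutation_null`, also
`RPConfig(null_scheme="independent")`). It admits exact enumeration — for
N <= 4 and k <= 2 all (N!)^k rank-column combinations can be listed and
the permutation estimate checked against the exact distribution — and the
test suite does exactly that.

It is not, however, the correct null for the all-pairs scheme: pairwise
comparisons that share a sample are strongly correlated, so the true null
RP distribution is wider than the independent-column one. Measured on a
pure-noise 5v5 simulation (N = 1000), calibrating against independent
columns yields ~19% of genes at p <= 0.05 instead of 5%. The default
(`null_scheme="experiment"`) therefore randomizes the gene order
independently *within each array* of the observed experiment and
recomputes the all-pairs rank matrix — B random experiments "with the
same number of replicates and genes as the real experiment". This
preserves the inter-column dependence, restores type-I calibration
(Kolmogorov–Smirnov distance of null p-values from uniform < 0.05 at
N = 1000, B = 1000, checked in the suite), and is distribution-free
because it permutes the observed values. By the up/down mirror symmetry
of ranks one null sample serves both directions.

Fold change is reported as 2^(mean_case − mean_control) of the log2
values; the per-probe group means are also carried in the result table so
R-I plot coordinates (log-ratio vs log-product) can be emitted.

### Sample-clustering QC

Distance between samples is 1 − Pearson correlation of their mean-centred
expression vectors; agglomeration is average linkage (UPGMA) via
`scipy.cluster.hierarchy`. The tree serializes to newick. A constant
sample vector makes the correlation undefined and raises an error naming
the sample.

## Gene-list construction

* **Detection filter** — two dialects, matching the two conventions in
  circulation: keep probes called Present in strictly more than a
  threshold fraction of all samples (default > 20%), or keep probes whose
  detection p-value is below a threshold (default 0.01) in strictly more
  than a fraction of samples (default > 10%).
* **Strict cutoffs** — p <= 1e-4 and pfp <= 0.05 by default, optionally a
  directional linear fold-change floor. Because pfp = E/rank can exceed
  1, `pfp_max = 1` is interpreted as "no pfp filter" so that fully
  relaxed cutoffs return the complete ranked list.
* **Length-targeted lists** — the top `target_length` probes by RP rank
  among those with pfp < 0.05; the false-positive cutoff is maintained
  even when lists are lengthened for cross-study comparability, and a
  shortfall is logged if fewer qualify.
* **Collapsing to symbols** — symbols are upper-cased and stripped; each
  symbol keeps its best (lowest) RP-ranked probe's statistics, unmapped
  probes are dropped with a logged count, and a symbol surfacing in both
  directions of one study is retained only where it ranks better
  (directional lists must be disjoint for meta-comparison). Best-rank-wins
  is deterministic and preserves the order semantics of the ranked lists.

Note on the strict p cutoff: p = E/N, so the smallest attainable p scales
inversely with the probe universe. p <= 1e-4 is meaningful on array-scale
universes (tens of thousands of probesets); on small simulated universes
an otherwise perfect gene cannot reach it, which is why the end-to-end
tests simulate ~2000-gene platforms.

## Cross-study comparison

All comparisons operate on collapsed symbol lists as given (no
cross-platform universe reduction). For direction d, matrix cell
(row X, col Y) is 100·|X_d ∩ Y_d| / N_Y — normalized by the **column**
study's list size. This denominator convention is the one that reconciles
the published pairwise cells with the printed shared-gene rows (9 shared
up genes: 9/117 → 7.7 as % of the current study, 9/115 → 7.8 as % of the
reanalysed bronchial list). The inverted cell uses X's
opposite-direction list. The ALL summary row gives the percentage of the
column list shared (or inverted) with at least one other study, counting
distinct genes — validated against the current-study column (16 distinct
genes of 117 → 13.7; 17 of 220 → 7.7). Full precision is kept
internally; display rounds half-up to one decimal.

The k-way signature intersects the selected studies' lists per direction,
orders the result by the first list's ranks, reports each member's
fold change in every list, and provides exclusive counts for all 2^k − 1
Venn regions.

## Enrichment statistics

Over-representation is the hypergeometric upper tail P(X >= k) for k list
hits in a K-member term within an N_u-symbol universe, with fold
enrichment (k/n)/(K/N_u), Benjamini–Hochberg FDR computed independently
within each annotation category, and an optional EASE-style variant that
scores the tail at k − 1 hits. Symbols outside a term's universe are
dropped with a logged count; terms under `min_count` hits are suppressed.

The running-sum enrichment score walks a ranked symbol list, adding the
normalized weight |w_i|^exponent at gene-set hits and subtracting
1/(L − n_hits) at misses; ES is the extremum of largest magnitude. A set
covering the whole list is uninformative and scores 0 by convention. The
p-value permutes the **gene set** (random same-size subsets of the ranked
list), p = (1 + #{|ES_null| >= |ES|})/(B + 1). Gene-set permutation is
chosen over phenotype permutation because at 5 vs 5 samples phenotype
permutation admits only 252 distinct relabelings, making the null too
coarse; this is a documented divergence from the original GSEA tool. The
ranking metric (RP rank or signed log fold change) is selectable and
recorded in the output.

## qPCR

Amplification efficiency is fit from a dilution standard curve:
E = 10^(−1/slope) of CT vs log10(relative input); perfect doubling gives
slope −3.3219, E = 2.0 (100%). Primer pairs outside 90–110% fail the
gate. Efficiencies are accepted as percentages (100 → 2.0) or linear
factors and stored as linear factors.

Relative expression uses the efficiency-corrected Pfaffl ratio
E_t^dCT_t / E_r^dCT_r with dCT = mean CT(control) − mean CT(case);
technical replicates are averaged before group means (replicate-mean
first; the alternative order is not used). With several reference genes
the per-reference ratios are combined by geometric mean — a symmetric,
scale-consistent rule the two-reference design (ACTB, GAPDH) does not
itself dictate. With all efficiencies 2 the ratio reduces exactly to the
classical 2^−ddCT. Down-regulation is displayed as the negative
reciprocal (0.3 → −3.3). Group tests are two-sided Student t and
Wilcoxon rank-sum on per-sample reference-normalized dCTs; the rank-sum
uses the uncorrected normal approximation so identical groups give
exactly p = 1.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with defaults at the motivating study's design point:

* 5 case vs 5 control samples; i.i.d. Gaussian noise on the log2 scale
  (0.25 log2 units), the simplest exchangeable null and the one the
  rank-based statistic assumes;
* planted effects of 1 log2 unit (2-fold) up and down, additive on every
  probe of a planted gene;
* probe multiplicity 1–3 per gene (85/12/3%), exercising symbol
  collapsing at roughly the published rate (a handful of 2–3-probeset
  genes per ~120-gene list);
* per-gene baselines N(8, 2) log2 units; probes more than 1 SD below the
  baseline mean are treated as unexpressed for detection simulation;
* detection calls Bernoulli per cell (P(present) = 0.95 expressed, 0.10
  unexpressed) with detection p-values U(0, 0.01) for present cells and
  U(0, 1) for absent ones, so both filter dialects are exercisable and
  mutually consistent;
* multi-study truth: a concordant core shared by all studies per
  direction (fraction configurable), a configurable fraction of the
  reference study's genes planted with inverted sign in the others
  (a modelling device for the inverted-expression phenomenon, not an
  estimate of inter-study variability), study-specific fill, and a
  common platform core of the symbol universe (default 80%);
* qPCR plates: CT = base − log_E(amount), case amount scaled by the
  planted fold change, Gaussian CT wobble shared by a sample's three
  technical replicates plus independent per-well noise.

What the generator does **not** emulate: intensity-dependent variance,
probe-level hybridization effects, batch effects, correlated gene
modules, or heavy-tailed noise. Passing tests therefore demonstrate the
statistical machinery is correct under its own assumptions, not that real
arrays satisfy those assumptions.

All generators take explicit integer seeds and are bit-reproducible; no
global random state is used anywhere.

## Numerical and design choices

* RP computed and compared in log space; E counts use a sorted pooled
  null and `searchsorted` with a 1e-12 relative slack so exactly tied
  null values count as "<=".
* Problem sizes in the test suite are chosen for desk-scale runs: null
  calibration at N = 1000 genes with B = 1000 permutations, recovery
  experiments at N = 1000–2000 with B = 100, exact enumeration only for
  N <= 4, k <= 2.
* Display rounding is half-up (not banker's) to one decimal, applied only
  at display; full precision is retained internally.
* The six-study published comparison data (list sizes, shared rows,
  combined lists, the 30-gene signature, qPCR panel) ship in
  `rpmeta.published` as data inputs. Reconstruction of the comparison
  from these rows pads each list with unique placeholder symbols to its
  printed size, so intersections involving the current study are exact
  while intersections among the other five studies (not printed) are
  empty — the reconstructed matrices are valid only where the printed
  data constrain them.
* The three-way reanalysis lists live in external supplements; the
  stand-in list set used to exercise the signature machinery is synthetic
  (printed 30-gene core plus unique padding) and labelled as such.

## Known limitations

* Paired-sample RP variants and multi-origin (cross-experiment) RP are
  out of scope; cross-study integration happens at the list level.
* The ALL-row definition (distinct genes shared with >= 1 other study) is
  validated only against the current-study column of the published
  matrix; other columns depend on unprinted inter-study overlaps.
* No alias/ortholog resolution at symbol harmonization beyond
  upper-casing; an explicit mapping table may be supplied.
* Accession-scale reproduction (the 133/255-probeset strict lists on the
  deposited dataset, the 616/303-gene reanalysis lists) requires the raw
  public repositories and a normalization stack upstream of this package;
  the pipeline consumes already-normalized matrices.
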