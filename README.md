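# rpmeta

Rank Products differential expression and cross-study gene-list
meta-analysis for two-group transcriptomics, with enrichment statistics,
qPCR relative quantification, and a synthetic multi-study generator.

## The problem

Small clinical microarray comparisons — the motivating case is nasal
epithelial brushings from five F508del-homozygous cystic fibrosis
patients versus five controls — have too few replicates for
parametric per-gene tests to be reliable, and independent studies of the
same contrast frequently disagree, with the same gene sometimes appearing
at *opposite* ends of two studies' rankings. This package provides the
analysis chain used to handle both problems:

1. **Rank Products (RP)** — a non-parametric statistic for consistent
   up-/down-regulation. For k = n_case × n_control pairwise sample
   comparisons, RP_g = (∏ᵢ r_gᵢ)^(1/k), the geometric mean of gene g's
   ranks by log-ratio in each comparison. Significance comes from B
   random-gene-order experiments: E_g = #{null RP ≤ RP_g}/B expected
   false positives, p_g = E_g/N, and the percentage of false prediction
   pfp_g = E_g/rank_g (RP's FDR analogue).
2. **Gene lists** — detection-call filtering (>20% present, or detection
   p < 0.01 in >10% of samples), strict cutoffs (p ≤ 1e-4, pfp ≤ 0.05),
   length-targeted extended lists, and probeset→symbol collapsing
   (best-ranked probe wins).
3. **Meta-comparison** — pairwise directional shared% and inverted%
   matrices (cell (X, Y) = 100·|X_d ∩ Y_d|/N_Y of the column study),
   ALL summary rows, shared-gene tables, and the k-way directional
   intersection signature with Venn-region counts.
4. **Enrichment** — hypergeometric over-representation with fold
   enrichment and per-category Benjamini–Hochberg FDR, and the weighted
   running-sum enrichment score (ES) with a gene-set-permutation p-value.
5. **qPCR validation** — standard-curve efficiencies E = 10^(−1/slope)
   with the 90–110% gate, and the efficiency-corrected Pfaffl ratio
   FC = E_target^ΔCT_target / E_ref^ΔCT_ref against multiple reference
   genes.

The synthetic generator (`rpmeta.synthetic`) plants known up/down genes
across several partially overlapping simulated studies — including
inverted-direction overlaps and MAS5-like detection calls — so the whole
chain runs and is tested with no downloads. `rpmeta.published` ships the
published six-study comparison summaries (list sizes, shared-gene rows,
the 30-gene airway signature, the qPCR panel) as data inputs.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
from rpmeta import (SimulationConfig, RPConfig, FilterConfig, generate_study,
                    rp_analyze, detection_filter, apply_cutoffs,
                    collapse_to_symbols)

cfg = SimulationConfig(n_genes=2000, n_up_true=40, n_down_true=40,
                       effect_log2fc=1.0, noise_sd_log2=0.25, seed=42)
study, truth = generate_study(cfg)
result = rp_analyze(study, RPConfig(n_permutations=1000, seed=42))
filtered = detection_filter(result, study, FilterConfig())
up = collapse_to_symbols(apply_cutoffs(filtered, FilterConfig(), "up"))
print(f"{len(up)} up-regulated symbols, "
      f"{len(up.symbols & truth.true_up)} of {len(truth.true_up)} planted")
print(up.entries.head(5).to_string(index=False))
```

prints

```
34 up-regulated symbols, 34 of 40 planted
 rank    probe_id   symbol       FC            p  pfp
    1 sim_p1116_1 GENE1116 3.029406 4.215852e-07  0.0
    2 sim_p1682_1 GENE1682 2.536459 4.215852e-07  0.0
    3  sim_p176_1 GENE0176 2.354566 4.215852e-07  0.0
    6  sim_p449_2 GENE0449 2.227802 4.215852e-07  0.0
    7 sim_p1592_1 GENE1592 2.192000 4.215852e-07  0.0
```

Of 40 planted 2-fold up-regulated genes, 34 survive the strict cutoffs
with no false positives; the `FC` column is the linear fold change
2^(Δ of log2 group means), `p` sits at the permutation floor 1/(B·N) for
the consistently top-ranked genes, and `pfp` estimates the false
prediction rate at each list position. Ranks are positions in the full
RP ordering, so gaps (here 4–5) mark probes removed by the detection
filter; `sim_p449_2` is the second probeset of its gene, kept as the
best-ranked one at symbol collapsing.

The same operations are exposed as a CLI:

```bash
rp-meta simulate --n-genes 2000 --seed 42 --out expr.tsv
rp-meta rankprod --matrix expr.tsv --permutations 1000 --seed 42 --out rp.tsv
rp-meta listbuild --result rp.tsv --direction up --out up.tsv
rp-meta compare --manifest studies.tsv --out-dir out/
```

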