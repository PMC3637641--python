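"""Enrichment statistics: over-representation and running-sum scores.

Two engines, both generic over any supplied annotation:

* hypergeometric over-representation with fold enrichment and
  Benjamini-Hochberg FDR (corrected independently within each annotation
  category), with an optional EASE-style conservative variant that scores
  the tail with one hit removed;
* a weighted Kolmogorov-Smirnov-type running sum over a ranked gene list
  (the GSEA enrichment score), with a gene-set-permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationTable:
    """One annotation term: a named symbol set within a universe."""

    term_id: str
    term_name: str
    category: str
    member_symbols: set[str]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.member_symbols <= self.universe:
            raise ValueError(
                f"term {self.term_id}: members outside the universe"
            )


@dataclass
class EnrichmentResult:
    """Per-term over-representation statistics.

    ``table`` columns: term_id, term_name, category, k (list hits),
    n (list size), K (term size), N_u (universe size), p, fold_enrichment,
    fdr.  fold_enrichment = (k/n) / (K/N_u).
    """

    table: pd.DataFrame


def hypergeom_enrich(
    list_symbols: set[str],
    terms: list[AnnotationTable],
    min_count: int = 2,
    ease: bool = False,
) -> EnrichmentResult:
    """Hypergeometric over-representation of a gene list in each term.

    p = P(X >= k) with X ~ Hypergeometric(N_u, K, n).  With ``ease=True``
    the tail is computed at k-1 hits (DAVID's EASE score), which penalises
    single-gene categories.  BH FDR is computed within each category; terms
    with k < ``min_count`` are suppressed before correction.
    """
    if not terms:
        return EnrichmentResult(pd.DataFrame())
    rows = []
    for t in terms:
        if not t.universe:
            raise ValueError(f"term {t.term_id}: empty universe")
        in_universe = {s for s in list_symbols if s in t.universe}
        dropped = len(list_symbols) - len(in_universe)
        n = len(in_universe)
        K = len(t.member_symbols)
        N_u = len(t.universe)
        k = len(in_universe & t.member_symbols)
        if k < min_count:
            continue
        k_eff = k - 1 if ease else k
        p = float(hypergeom.sf(k_eff - 1, N_u, K, n))
        fe = (k / n) / (K / N_u) if n and K else 0.0
        rows.append(
            dict(term_id=t.term_id, term_name=t.term_name, category=t.category,
                 k=k, n=n, K=K, N_u=N_u, p=min(p, 1.0), fold_enrichment=fe,
                 dropped_symbols=dropped)
        )
    if not rows:
        return EnrichmentResult(pd.DataFrame())
    df = pd.DataFrame(rows)
    df["fdr"] = np.nan
    for cat, idx in df.groupby("category").groups.items():
        df.loc[idx, "fdr"] = multipletests(df.loc[idx, "p"], method="fdr_bh")[1]
    df = df.sort_values(["category", "p"]).reset_index(drop=True)
    return EnrichmentResult(df)


@dataclass
class GseaResult:
    """Running-sum enrichment of one gene set in a ranked list."""

    gene_set_name: str
    es: float
    running_sum: np.ndarray
    hit_positions: list[int]
    p: float | None = None
    weight_exponent: float = 1.0


def gsea_enrichment_score(
    ranked_symbols: list[str],
    gene_set: set[str],
    weights: dict[str, float] | None = None,
    weight_exponent: float = 1.0,
    gene_set_name: str = "gene_set",
) -> GseaResult:
    """Weighted running-sum enrichment score.

    Walking the ranked list, the sum increments by |w_i|^exponent
    (normalized over hits) at gene-set members and decrements by
    1/(L - n_hits) at non-members; ES is the extremum of largest magnitude.
    With ``weight_exponent=0`` or no weights every hit counts equally
    (the classical KS statistic).  A gene set covering the entire list is
    uninformative and scores ES = 0 by convention.
    """
    L = len(ranked_symbols)
    hits = np.array([s in gene_set for s in ranked_symbols])
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if n_hits == L:
        return GseaResult(gene_set_name, 0.0, np.zeros(L),
                          list(range(L)), weight_exponent=weight_exponent)
    if weights is None:
        w = np.ones(L)
    else:
        w = np.array([abs(weights.get(s, 0.0)) for s in ranked_symbols])
    w = np.abs(w) ** weight_exponent
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        raise ValueError("all hit weights are zero")
    step = np.where(hits, hit_w / denom, -1.0 / (L - n_hits))
    running = np.cumsum(step)
    es = running[np.argmax(np.abs(running))]
    return GseaResult(
        gene_set_name=gene_set_name,
        es=float(es),
        running_sum=running,
        hit_positions=list(np.flatnonzero(hits)),
        weight_exponent=weight_exponent,
    )


def gsea_pvalue(
    result: GseaResult,
    ranked_symbols: list[str],
    gene_set_size: int,
    n_permutations: int = 1000,
    seed: int = 0,
    weights: dict[str, float] | None = None,
) -> float:
    """Gene-set-permutation p-value for an enrichment score.

    Null scores come from random same-size subsets of the ranked list;
    p = (1 + #{|ES_null| >= |ES|}) / (B + 1).
    """
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    L = len(ranked_symbols)
    if gene_set_size > L:
        raise ValueError("gene set larger than ranked list")
    rng = np.random.default_rng(seed)
    exceed = 0
    arr = np.asarray(ranked_symbols, dtype=object)
    for _ in range(n_permutations):
        null_set = set(arr[rng.choice(L, size=gene_set_size, replace=False)])
        null = gsea_enrichment_score(
            ranked_symbols, null_set, weights=weights,
            weight_exponent=result.weight_exponent,
        )
        if abs(null.es) >= abs(result.es):
            exceed += 1
    return (1 + exceed) / (n_permutations + 1)
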