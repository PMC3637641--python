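"""qPCR relative quantification: standard curves and the Pfaffl method.

Amplification efficiency E (linear factor; 2.0 = perfect doubling = 100%)
is estimated from a dilution standard curve as E = 10^(-1/slope) of the
least-squares fit of CT against log10(relative input).  Primer pairs
outside the 90-110% efficiency window fail the quality gate.  Relative
expression between groups uses the efficiency-corrected Pfaffl ratio

    FC = E_target^dCT_target / E_ref^dCT_ref,    dCT = mean CT(control) - mean CT(case),

with technical replicates averaged before group means and the geometric
mean taken over multiple reference genes.  With all efficiencies equal to
2 this reduces exactly to the classical 2^-ddCT method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rankprod import CASE, CONTROL

EFFICIENCY_GATE = (0.90, 1.10)  # fractional efficiency window (90-110%)


@dataclass
class QPCRPlate:
    """Long-format CT measurements with per-gene efficiencies.

    ``records`` columns: gene, sample, group (case/control), replicate, CT.
    ``efficiencies`` are linear amplification factors in (1, 2.2].
    """

    records: pd.DataFrame
    efficiencies: dict[str, float]
    reference_genes: set[str]

    def __post_init__(self) -> None:
        if not self.reference_genes:
            raise ValueError("at least one reference gene required")
        missing = self.reference_genes - set(self.records["gene"])
        if missing:
            raise ValueError(f"reference genes not on plate: {sorted(missing)}")
        for g, e in self.efficiencies.items():
            if not (1.0 < e <= 2.2):
                raise ValueError(f"efficiency for {g} out of range (1, 2.2]: {e}")
        if (self.records["CT"] <= 0).any():
            raise ValueError("CT values must be positive")
        bad = set(self.records["group"]) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")

    def efficiency(self, gene: str) -> float:
        try:
            return self.efficiencies[gene]
        except KeyError:
            raise KeyError(f"no efficiency recorded for {gene}") from None

    def replicate_means(self, gene: str) -> pd.DataFrame:
        """Mean CT over technical replicates, one row per sample."""
        sub = self.records[self.records["gene"] == gene]
        if sub.empty:
            raise ValueError(f"gene {gene} not on plate")
        return (
            sub.groupby(["sample", "group"], as_index=False)["CT"].mean()
        )


def efficiency_to_linear(value: float) -> float:
    """Accept an efficiency as a percentage (100 -> 2.0) or linear factor."""
    if value > 2.2:  # percentages: 90..110
        return 1.0 + value / 100.0
    return value


@dataclass
class StandardCurve:
    """Dilution-series calibration of one primer pair."""

    dilution_inputs: list[float]
    mean_cts: list[float]
    slope: float
    intercept: float
    efficiency: float  # linear factor
    r_squared: float

    @property
    def efficiency_percent(self) -> float:
        return (self.efficiency - 1.0) * 100.0

    @property
    def passes_gate(self) -> bool:
        lo, hi = EFFICIENCY_GATE
        return lo <= self.efficiency - 1.0 <= hi


def efficiency_from_standard_curve(
    dilutions: list[float], cts: list[float]
) -> StandardCurve:
    """Fit CT against log10(relative input) of a dilution series.

    ``dilutions`` are relative template amounts (e.g. 1, 0.2, 0.04 for a
    1:5 series), strictly decreasing.  E = 10^(-1/slope); a perfect
    doubling assay has slope -3.3219 and E = 2.0 (100%).
    """
    if len(dilutions) != len(cts):
        raise ValueError("dilutions and CTs must be parallel")
    if len(dilutions) < 3:
        raise ValueError("need at least 3 dilution points")
    d = np.asarray(dilutions, dtype=float)
    if np.any(np.diff(d) >= 0):
        raise ValueError("dilution inputs must be strictly decreasing")
    if np.any(d <= 0):
        raise ValueError("dilution inputs must be positive")
    fit = stats.linregress(np.log10(d), np.asarray(cts, dtype=float))
    if fit.slope >= 0:
        raise ValueError("non-negative standard-curve slope; check input order")
    eff = 10.0 ** (-1.0 / fit.slope)
    return StandardCurve(
        dilution_inputs=list(d),
        mean_cts=list(cts),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(eff),
        r_squared=float(fit.rvalue ** 2),
    )


def _group_mean_ct(plate: QPCRPlate, gene: str) -> tuple[float, float]:
    means = plate.replicate_means(gene)
    by_group = means.groupby("group")["CT"].mean()
    for grp in (CASE, CONTROL):
        if grp not in by_group.index:
            raise ValueError(f"gene {gene}: no {grp} samples")
    return float(by_group[CASE]), float(by_group[CONTROL])


def pfaffl_fold_change(plate: QPCRPlate, target: str) -> float:
    """Efficiency-corrected relative fold change (case vs control).

    Returns the raw ratio (>0).  Use :func:`display_fold_change` for the
    negative-reciprocal display convention for down-regulation.
    """
    case_t, ctrl_t = _group_mean_ct(plate, target)
    dct_t = ctrl_t - case_t
    e_t = plate.efficiency(target)
    ratios = []
    for ref in sorted(plate.reference_genes):
        case_r, ctrl_r = _group_mean_ct(plate, ref)
        dct_r = ctrl_r - case_r
        e_r = plate.efficiency(ref)
        ratios.append((e_t ** dct_t) / (e_r ** dct_r))
    return float(np.exp(np.mean(np.log(ratios))))


def display_fold_change(fc: float) -> float:
    """Down-regulation shown as a negative reciprocal (0.3 -> -3.3)."""
    if fc <= 0:
        raise ValueError("fold change must be positive")
    return fc if fc >= 1.0 else -1.0 / fc


def _normalized_dcts(plate: QPCRPlate, target: str) -> pd.DataFrame:
    """Per-sample reference-normalized dCT: CT_target - mean over refs."""
    t = plate.replicate_means(target).rename(columns={"CT": "ct_target"})
    refs = [
        plate.replicate_means(r)[["sample", "CT"]].rename(columns={"CT": f"ct_{r}"})
        for r in sorted(plate.reference_genes)
    ]
    merged = t
    for r in refs:
        merged = merged.merge(r, on="sample", how="inner")
    ref_cols = [c for c in merged.columns if c.startswith("ct_") and c != "ct_target"]
    merged["dct"] = merged["ct_target"] - merged[ref_cols].mean(axis=1)
    return merged[["sample", "group", "dct"]]


def group_difference_test(plate: QPCRPlate, target: str) -> dict[str, float]:
    """Two-sided t and Wilcoxon rank-sum tests on per-sample dCTs."""
    d = _normalized_dcts(plate, target)
    case = d.loc[d["group"] == CASE, "dct"].to_numpy()
    ctrl = d.loc[d["group"] == CONTROL, "dct"].to_numpy()
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need at least 2 samples per group")
    t_p = float(stats.ttest_ind(case, ctrl).pvalue)
    # ranksums (no tie/continuity correction): identical groups give p = 1
    w_p = float(stats.ranksums(case, ctrl).pvalue)
    return {"t": t_p, "ranksum": w_p}
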