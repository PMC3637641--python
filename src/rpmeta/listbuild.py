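"""From RP statistics to directional gene lists.

Turns a :class:`~rpmeta.rankprod.RankProductResult` into the ranked,
directional gene lists downstream meta-analysis consumes: a detection-call
filter (two dialects: fraction of samples called present, or fraction with
detection p below a threshold), strict p/pfp/fold-change cutoffs,
length-targeted extended lists, and collapsing of probesets to unique gene
symbols (best-ranked probe wins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .rankprod import Direction, ExpressionStudy, RankProductResult

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Cutoffs for list construction.

    Defaults are the strict thresholds: p <= 1e-4, pfp (FDR) <= 0.05, with a
    detection filter of >20% present calls across all samples.
    """

    p_max: float = 1e-4
    pfp_max: float = 0.05
    fc_min: float | None = None
    detection_mode: Literal["fraction_present", "fraction_detected_p"] = (
        "fraction_present"
    )
    detection_threshold: float = 0.2
    detection_p: float = 0.01
    target_length: int | None = None

    def __post_init__(self) -> None:
        for name, v in (("p_max", self.p_max), ("pfp_max", self.pfp_max),
                        ("detection_threshold", self.detection_threshold),
                        ("detection_p", self.detection_p)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fc_min is not None and self.fc_min < 1.0:
            raise ValueError("fc_min is a linear fold change >= 1")


@dataclass
class GeneList:
    """Ordered directional list of regulated entries for one study.

    ``entries`` columns: rank, probe_id, symbol, FC, p, pfp — ordered by
    ascending RP rank.  After :func:`collapse_to_symbols` the symbols are
    unique and ``collapsed`` is set.
    """

    study_name: str
    direction: Direction
    entries: pd.DataFrame
    collapsed: bool = False
    universe_size: int = 0

    def __post_init__(self) -> None:
        ranks = self.entries["rank"].to_numpy()
        if len(ranks) > 1 and np.any(np.diff(ranks) < 0):
            raise ValueError("entries must be ordered by ascending rank")
        if self.collapsed and self.entries["symbol"].duplicated().any():
            raise ValueError("collapsed list has duplicated symbols")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def symbols(self) -> set[str]:
        return set(self.entries["symbol"])


def _present_fraction(study: ExpressionStudy, mode: str, detection_p: float) -> np.ndarray:
    if mode == "fraction_present":
        if study.detection is None:
            raise ValueError("fraction_present filter needs detection calls")
        return (np.asarray(study.detection) == "P").mean(axis=1)
    if mode == "fraction_detected_p":
        if study.detection_p is None:
            raise ValueError("fraction_detected_p filter needs detection p-values")
        return (np.asarray(study.detection_p, dtype=float) < detection_p).mean(axis=1)
    raise ValueError(f"unknown detection mode {mode!r}")


def detection_filter(
    result: RankProductResult, study: ExpressionStudy, config: FilterConfig
) -> RankProductResult:
    """Drop probes failing the detection-call rule from both directions.

    ``fraction_present``: keep probes called present in strictly more than
    ``detection_threshold`` of all samples.  ``fraction_detected_p``: keep
    probes with detection p < ``detection_p`` in strictly more than
    ``detection_threshold`` of samples.
    """
    frac = _present_fraction(study, config.detection_mode, config.detection_p)
    by_probe = dict(zip(study.probe_ids, frac))
    keep_mask = result.table["probe_id"].map(by_probe).to_numpy() > config.detection_threshold
    table = result.table[keep_mask].reset_index(drop=True)
    logger.info(
        "detection filter (%s > %g): %d of %d probes retained",
        config.detection_mode, config.detection_threshold,
        keep_mask.sum(), len(keep_mask),
    )
    return RankProductResult(
        table=table,
        n_genes=int(keep_mask.sum()),
        k=result.k,
        n_permutations=result.n_permutations,
        seed=result.seed,
        study_name=result.study_name,
    )


def _direction_entries(result: RankProductResult, direction: Direction) -> pd.DataFrame:
    d = result.direction_table(direction)
    return pd.DataFrame(
        {
            "rank": d[f"rank_{direction}"],
            "probe_id": d["probe_id"],
            "symbol": d["symbol"],
            "FC": d["FC"],
            "p": d[f"p_{direction}"],
            "pfp": d[f"pfp_{direction}"],
        }
    )


def apply_cutoffs(
    result: RankProductResult, config: FilterConfig, direction: Direction
) -> GeneList:
    """Strict list: keep probes with p <= p_max, pfp <= pfp_max, and (if
    configured) fold change beyond ``fc_min`` in the list's direction."""
    e = _direction_entries(result, direction)
    keep = e["p"] <= config.p_max
    # pfp = E/rank can exceed 1, so pfp_max=1 means "no pfp filtering"
    if config.pfp_max < 1.0:
        keep &= e["pfp"] <= config.pfp_max
    if config.fc_min is not None:
        if direction == "up":
            keep &= e["FC"] >= config.fc_min
        else:
            keep &= e["FC"] <= 1.0 / config.fc_min
    entries = e[keep].reset_index(drop=True)
    logger.info(
        "%s/%s cutoffs p<=%g pfp<=%g: %d of %d probes",
        result.study_name, direction, config.p_max, config.pfp_max,
        len(entries), len(e),
    )
    return GeneList(
        study_name=result.study_name,
        direction=direction,
        entries=entries,
        universe_size=result.n_genes,
    )


def size_targeted_list(
    result: RankProductResult,
    direction: Direction,
    target_length: int,
    pfp_max: float = 0.05,
) -> GeneList:
    """Extended list: top ``target_length`` probes by RP rank among those
    with pfp below ``pfp_max`` (the false-positive cutoff is maintained even
    when the list is lengthened).  If fewer qualify, all are returned and a
    shortfall is logged."""
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    e = _direction_entries(result, direction)
    qualifying = e[e["pfp"] < pfp_max]
    if len(qualifying) < target_length:
        logger.warning(
            "%s/%s: only %d probes qualify at pfp<%g (target %d)",
            result.study_name, direction, len(qualifying), pfp_max, target_length,
        )
    entries = qualifying.head(target_length).reset_index(drop=True)
    return GeneList(
        study_name=result.study_name,
        direction=direction,
        entries=entries,
        universe_size=result.n_genes,
    )


def normalize_symbol(symbol: str) -> str:
    """Case-fold to upper case and strip whitespace for comparison."""
    return symbol.strip().upper()


def collapse_to_symbols(
    gene_list: GeneList, mapping: dict[str, str] | None = None
) -> GeneList:
    """Collapse probesets to unique gene symbols.

    Each symbol keeps the statistics of its best (lowest) RP-ranked probe;
    output order is by that rank.  Probes with no symbol (empty/NaN after
    mapping) are dropped and their count logged.
    """
    e = gene_list.entries.copy()
    if mapping is not None:
        e["symbol"] = e["probe_id"].map(mapping)
    e["symbol"] = e["symbol"].map(
        lambda s: normalize_symbol(s) if isinstance(s, str) else ""
    )
    unmapped = (e["symbol"] == "").sum()
    if unmapped:
        logger.info(
            "%s/%s: dropped %d un-named probesets at collapse",
            gene_list.study_name, gene_list.direction, unmapped,
        )
    e = e[e["symbol"] != ""]
    # entries are rank-ordered, so first occurrence is the best-ranked probe
    e = e.drop_duplicates(subset="symbol", keep="first").reset_index(drop=True)
    return GeneList(
        study_name=gene_list.study_name,
        direction=gene_list.direction,
        entries=e,
        collapsed=True,
        universe_size=gene_list.universe_size,
    )


def resolve_direction_conflicts(up: GeneList, down: GeneList) -> tuple[GeneList, GeneList]:
    """Keep a symbol only in the direction where it ranks better.

    After collapsing, a symbol can surface in both directional lists of one
    study (different probes); directional lists must be disjoint for
    meta-comparison, so the worse-ranked occurrence is removed and logged.
    """
    common = up.symbols & down.symbols
    if not common:
        return up, down
    logger.info(
        "%s: %d symbols in both directions; keeping better rank",
        up.study_name, len(common),
    )
    up_rank = dict(zip(up.entries["symbol"], up.entries["rank"]))
    down_rank = dict(zip(down.entries["symbol"], down.entries["rank"]))
    drop_up = {s for s in common if up_rank[s] > down_rank[s]}
    drop_down = common - drop_up
    new_up = replace(
        up, entries=up.entries[~up.entries["symbol"].isin(drop_up)].reset_index(drop=True)
    )
    new_down = replace(
        down,
        entries=down.entries[~down.entries["symbol"].isin(drop_down)].reset_index(drop=True),
    )
    return new_up, new_down
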