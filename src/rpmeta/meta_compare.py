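"""Cross-study directional meta-analysis of gene lists.

Given per-study up/down gene lists collapsed to symbols, computes pairwise
directional overlap: the fraction of one study's list regulated in the same
direction (shared) or the opposite direction (inverted) in another study;
the per-direction comparison matrix with ALL summary rows (fraction of a
list shared with at least one other study); per-study shared-gene tables
against a reference study with the combined >=2-study list; and the k-way
directional intersection signature with full Venn-region counts.

Convention: matrix cell (row X, col Y) is the intersection count as a
percentage of *column* study Y's list size, displayed rounded half-up to
one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import pandas as pd

from .listbuild import GeneList
from .rankprod import Direction


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding: 0.25 -> 0.3 at one decimal (not banker's)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class StudyListSet:
    """Up and down collapsed gene lists for each of several studies."""

    lists: dict[str, dict[Direction, GeneList]]

    def __post_init__(self) -> None:
        for name, pair in self.lists.items():
            up, down = pair["up"], pair["down"]
            if common := (up.symbols & down.symbols):
                raise ValueError(
                    f"study {name}: {len(common)} symbols in both directions"
                )

    @property
    def study_names(self) -> list[str]:
        return list(self.lists)

    def gene_list(self, study: str, direction: Direction) -> GeneList:
        return self.lists[study][direction]

    def size(self, study: str, direction: Direction) -> int:
        return len(self.lists[study][direction])


@dataclass
class ComparisonMatrix:
    """Pairwise shared/inverted percentages for one direction.

    ``shared_pct.loc[X, Y]`` = 100 * |X_d intersect Y_d| / N_Y(d);
    ``inverted_pct.loc[X, Y]`` uses X's opposite-direction list.  The
    ``all_shared`` / ``all_inverted`` rows give, per column study, the
    percentage of its list shared (or inverted) with at least one other
    study.  Full precision is kept; use :meth:`rounded` for display.
    """

    direction: Direction
    shared_pct: pd.DataFrame
    inverted_pct: pd.DataFrame
    all_shared: pd.Series
    all_inverted: pd.Series
    denominators: dict[str, int]

    def rounded(self, decimals: int = 1) -> "ComparisonMatrix":
        r = lambda df: df.map(lambda v: round_half_up(v, decimals))
        return ComparisonMatrix(
            direction=self.direction,
            shared_pct=r(self.shared_pct),
            inverted_pct=r(self.inverted_pct),
            all_shared=self.all_shared.map(lambda v: round_half_up(v, decimals)),
            all_inverted=self.all_inverted.map(lambda v: round_half_up(v, decimals)),
            denominators=dict(self.denominators),
        )


@dataclass
class SignatureResult:
    """Genes regulated in the same direction across all selected lists."""

    up_symbols: list[str]
    down_symbols: list[str]
    membership: pd.DataFrame  # symbol, direction, then per-list FC columns
    venn_counts: dict[Direction, dict[frozenset, int]]

    @property
    def n_up(self) -> int:
        return len(self.up_symbols)

    @property
    def n_down(self) -> int:
        return len(self.down_symbols)


def _require_collapsed(*lists: GeneList) -> None:
    for gl in lists:
        if not gl.collapsed:
            raise ValueError(
                f"{gl.study_name}/{gl.direction} list is not collapsed to symbols"
            )


def directional_overlap(
    list_x: GeneList, list_y: GeneList, opposite: bool = False
) -> tuple[int, float]:
    """Overlap of X with Y as a count and a percentage of Y's list size.

    With ``opposite=True``, X is taken to be the opposite-direction list,
    i.e. the result counts Y genes that appear inverted in X.
    """
    _require_collapsed(list_x, list_y)
    count = len(list_x.symbols & list_y.symbols)
    pct = 100.0 * count / len(list_y) if len(list_y) else 0.0
    return count, pct


def comparison_matrix(listset: StudyListSet, direction: Direction) -> ComparisonMatrix:
    """All ordered-pair shared and inverted percentages for one direction."""
    names = listset.study_names
    if len(names) < 2:
        raise ValueError("need at least 2 studies")
    opp: Direction = "down" if direction == "up" else "up"
    shared = pd.DataFrame(0.0, index=names, columns=names)
    inverted = pd.DataFrame(0.0, index=names, columns=names)
    for x in names:
        for y in names:
            if x == y:
                shared.loc[x, y] = 100.0
                inverted.loc[x, y] = 0.0
                continue
            _, shared.loc[x, y] = directional_overlap(
                listset.gene_list(x, direction), listset.gene_list(y, direction)
            )
            _, inverted.loc[x, y] = directional_overlap(
                listset.gene_list(x, opp), listset.gene_list(y, direction),
                opposite=True,
            )
    all_shared, all_inverted = {}, {}
    for y in names:
        y_syms = listset.gene_list(y, direction).symbols
        n_y = len(y_syms)
        others_same = set().union(
            *(listset.gene_list(x, direction).symbols for x in names if x != y)
        )
        others_opp = set().union(
            *(listset.gene_list(x, opp).symbols for x in names if x != y)
        )
        all_shared[y] = 100.0 * len(y_syms & others_same) / n_y if n_y else 0.0
        all_inverted[y] = 100.0 * len(y_syms & others_opp) / n_y if n_y else 0.0
    return ComparisonMatrix(
        direction=direction,
        shared_pct=shared,
        inverted_pct=inverted,
        all_shared=pd.Series(all_shared),
        all_inverted=pd.Series(all_inverted),
        denominators={y: listset.size(y, direction) for y in names},
    )


def _venn_counts(symbol_sets: dict[str, set[str]]) -> dict[frozenset, int]:
    """Exclusive symbol count for each of the 2^k - 1 Venn regions."""
    counts: dict[frozenset, int] = {
        frozenset(members): 0
        for r in range(1, len(symbol_sets) + 1)
        for members in combinations(symbol_sets, r)
    }
    for sym in set().union(*symbol_sets.values()):
        region = frozenset(n for n, s in symbol_sets.items() if sym in s)
        counts[region] += 1
    return counts


def intersect_signature(
    listset: StudyListSet, required_lists: list[str] | None = None
) -> SignatureResult:
    """Molecular signature: symbols regulated in the same direction in every
    selected study, ordered by the first study's rank, with per-list fold
    changes and the full Venn-region breakdown."""
    names = required_lists if required_lists is not None else listset.study_names
    if not names:
        raise ValueError("empty study selector")
    for n in names:
        _require_collapsed(listset.gene_list(n, "up"), listset.gene_list(n, "down"))

    venn: dict[Direction, dict[frozenset, int]] = {}
    sig: dict[Direction, list[str]] = {}
    for direction in ("up", "down"):
        sets = {n: listset.gene_list(n, direction).symbols for n in names}
        venn[direction] = _venn_counts(sets)
        core = set.intersection(*sets.values())
        first = listset.gene_list(names[0], direction).entries
        ordered = [s for s in first["symbol"] if s in core]
        sig[direction] = ordered

    rows = []
    for direction in ("up", "down"):
        for sym in sig[direction]:
            row: dict = {"symbol": sym, "direction": direction}
            for n in names:
                e = listset.gene_list(n, direction).entries
                row[f"FC_{n}"] = float(e.loc[e["symbol"] == sym, "FC"].iloc[0])
            rows.append(row)
    membership = pd.DataFrame(rows)
    return SignatureResult(
        up_symbols=sig["up"],
        down_symbols=sig["down"],
        membership=membership,
        venn_counts=venn,
    )


def shared_gene_table(
    listset: StudyListSet, reference_study: str
) -> tuple[dict[str, dict[Direction, list[str]]], dict[Direction, list[str]]]:
    """Per-study genes shared same-direction with a reference study, plus the
    combined list of genes shared between any two or more studies.

    Returns ``(per_study, combined)`` where ``per_study[study][direction]``
    are the reference-shared symbols in the reference study's rank order and
    ``combined[direction]`` is the sorted union over all study pairs.
    """
    names = listset.study_names
    per_study: dict[str, dict[Direction, list[str]]] = {}
    for other in names:
        if other == reference_study:
            continue
        per_study[other] = {}
        for direction in ("up", "down"):
            ref = listset.gene_list(reference_study, direction)
            oth = listset.gene_list(other, direction)
            _require_collapsed(ref, oth)
            common = ref.symbols & oth.symbols
            per_study[other][direction] = [
                s for s in ref.entries["symbol"] if s in common
            ]
    combined: dict[Direction, list[str]] = {}
    for direction in ("up", "down"):
        union: set[str] = set()
        for a, b in combinations(names, 2):
            union |= (
                listset.gene_list(a, direction).symbols
                & listset.gene_list(b, direction).symbols
            )
        combined[direction] = sorted(union)
    return per_study, combined
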