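"""Tabular readers and writers for every artifact the pipeline exchanges.

All formats are plain delimiter-separated text with one header line:
expression matrices (first columns probe_id and symbol, then one column
per sample), companion group-label and detection matrices, RP result
tables, gene lists, GMT gene-set files, and long-format qPCR plates.
Every writer's output is re-readable by the matching reader.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationTable
from .listbuild import GeneList
from .rankprod import ExpressionStudy, RankProductResult

SEP = "\t"


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------


def write_expression_study(study: ExpressionStudy, path: str | os.PathLike) -> None:
    """Write matrix (+ optional detection matrices) as TSV.

    Writes ``<path>`` (expression), ``<path base>.groups.tsv`` (sample,
    group) and, if present, ``.calls.tsv`` / ``.detp.tsv``.
    """
    path = Path(path)
    base = path.with_suffix("")
    df = pd.DataFrame(study.matrix, columns=study.sample_ids)
    df.insert(0, "symbol", study.symbols)
    df.insert(0, "probe_id", study.probe_ids)
    df.to_csv(path, sep=SEP, index=False, float_format="%.10g")
    pd.DataFrame(
        {"sample": study.sample_ids, "group": study.group_labels}
    ).to_csv(base.with_suffix(".groups.tsv"), sep=SEP, index=False)
    if study.detection is not None:
        calls = pd.DataFrame(study.detection, columns=study.sample_ids)
        calls.insert(0, "probe_id", study.probe_ids)
        calls.to_csv(base.with_suffix(".calls.tsv"), sep=SEP, index=False)
    if study.detection_p is not None:
        detp = pd.DataFrame(study.detection_p, columns=study.sample_ids)
        detp.insert(0, "probe_id", study.probe_ids)
        detp.to_csv(base.with_suffix(".detp.tsv"), sep=SEP, index=False,
                    float_format="%.10g")


def read_expression_matrix(
    path: str | os.PathLike,
    groups_path: str | os.PathLike | None = None,
    calls_path: str | os.PathLike | None = None,
    detp_path: str | os.PathLike | None = None,
    study_name: str | None = None,
) -> ExpressionStudy:
    """Parse an expression matrix plus its companion files.

    Companion paths default to the ``.groups.tsv`` / ``.calls.tsv`` /
    ``.detp.tsv`` siblings written by :func:`write_expression_study`
    (detection files only if they exist).
    """
    path = Path(path)
    base = path.with_suffix("")
    df = pd.read_csv(path, sep=SEP, dtype={"probe_id": str, "symbol": str})
    if df.columns[0] != "probe_id" or df.columns[1] != "symbol":
        raise ValueError(
            f"{path}: first two columns must be probe_id and symbol, "
            f"got {list(df.columns[:2])}"
        )
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if not dup.empty:
        row = int(dup.index[0]) + 2  # 1-based, counting the header
        raise ValueError(f"{path}: duplicated probe id {dup.iloc[0]!r} at row {row}")
    sample_ids = list(df.columns[2:])
    body = df[sample_ids]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {body.iat[r, c]!r} at row {r + 2}"
        )
    if numeric.isna().any().any():
        r = int(np.argwhere(numeric.isna().to_numpy())[0][0])
        raise ValueError(f"{path}: missing value at row {r + 2} (ragged row?)")

    groups_path = Path(groups_path) if groups_path else base.with_suffix(".groups.tsv")
    gdf = pd.read_csv(groups_path, sep=SEP, dtype=str)
    gmap = dict(zip(gdf["sample"], gdf["group"]))
    try:
        labels = [gmap[s] for s in sample_ids]
    except KeyError as e:
        raise ValueError(f"{groups_path}: no group label for sample {e}") from None

    detection = detection_p = None
    calls_path = Path(calls_path) if calls_path else base.with_suffix(".calls.tsv")
    if calls_path.exists():
        cdf = pd.read_csv(calls_path, sep=SEP, dtype=str)
        detection = cdf[sample_ids].to_numpy(dtype=object)
    detp_path = Path(detp_path) if detp_path else base.with_suffix(".detp.tsv")
    if detp_path.exists():
        pdf = pd.read_csv(detp_path, sep=SEP)
        detection_p = pdf[sample_ids].to_numpy(dtype=float)

    symbols = df["symbol"].fillna("").tolist()
    return ExpressionStudy(
        probe_ids=df["probe_id"].tolist(),
        symbols=symbols,
        matrix=numeric.to_numpy(dtype=float),
        group_labels=labels,
        sample_ids=sample_ids,
        detection=detection,
        detection_p=detection_p,
        study_name=study_name or path.stem,
    )


# ---------------------------------------------------------------------------
# RP results and gene lists
# ---------------------------------------------------------------------------


def write_rp_result(result: RankProductResult, path: str | os.PathLike) -> None:
    result.table.to_csv(path, sep=SEP, index=False, float_format="%.10g")


def read_rp_result(
    path: str | os.PathLike,
    n_permutations: int = 0,
    seed: int = 0,
    k: int = 0,
    study_name: str | None = None,
) -> RankProductResult:
    table = pd.read_csv(path, sep=SEP, dtype={"probe_id": str, "symbol": str})
    table["symbol"] = table["symbol"].fillna("")
    return RankProductResult(
        table=table, n_genes=len(table), k=k, n_permutations=n_permutations,
        seed=seed, study_name=study_name or Path(path).stem,
    )


def write_gene_list(gene_list: GeneList, path: str | os.PathLike) -> None:
    out = gene_list.entries.copy()
    out.insert(0, "direction", gene_list.direction)
    out.insert(0, "study", gene_list.study_name)
    out.to_csv(path, sep=SEP, index=False, float_format="%.10g")


def read_gene_list(path: str | os.PathLike, collapsed: bool | None = None) -> GeneList:
    """Read a gene list table (study, direction, rank, probe_id, symbol,
    FC, p, pfp).  Direction tokens are case-normalized; ``collapsed`` is
    inferred from symbol uniqueness unless given."""
    df = pd.read_csv(path, sep=SEP, dtype={"probe_id": str, "symbol": str})
    for i, d in enumerate(df["direction"]):
        if str(d).strip().lower() not in ("up", "down"):
            raise ValueError(
                f"{path}: unknown direction {d!r} at row {i + 2}"
            )
    direction = str(df["direction"].iloc[0]).strip().lower()
    study = str(df["study"].iloc[0])
    entries = df[["rank", "probe_id", "symbol", "FC", "p", "pfp"]].copy()
    if collapsed is None:
        collapsed = not entries["symbol"].duplicated().any()
    return GeneList(
        study_name=study, direction=direction, entries=entries,  # type: ignore[arg-type]
        collapsed=collapsed, universe_size=len(entries),
    )


# ---------------------------------------------------------------------------
# gene sets (GMT) and annotation tables
# ---------------------------------------------------------------------------


def read_gmt(
    path: str | os.PathLike,
    universe: set[str] | None = None,
    category: str = "gene_set",
) -> list[AnnotationTable]:
    """Parse a GMT file: term <tab> description <tab> member symbols.

    Without an explicit ``universe``, the union of all member symbols is
    used as the background.
    """
    terms = []
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and "
                    "at least one member"
                )
            members = {m.strip().upper() for m in parts[2:] if m.strip()}
            if not members:
                raise ValueError(f"{path}:{lineno}: empty member list")
            raw.append((parts[0], parts[1], members))
    u = universe if universe is not None else set().union(
        *(m for _, _, m in raw)
    ) if raw else set()
    for term_id, desc, members in raw:
        terms.append(
            AnnotationTable(
                term_id=term_id, term_name=desc or term_id, category=category,
                member_symbols=members & u, universe=u,
            )
        )
    return terms


def read_annotation_table(
    path: str | os.PathLike,
    universe: set[str] | None = None,
    category: str = "annotation",
) -> list[AnnotationTable]:
    """Two-column term <tab> symbol flat file -> annotation terms."""
    df = pd.read_csv(path, sep=SEP, header=None, names=["term", "symbol"],
                     dtype=str, comment="#")
    groups = df.groupby("term")["symbol"].apply(
        lambda s: {x.strip().upper() for x in s}
    )
    u = universe if universe is not None else set().union(*groups) if len(groups) else set()
    return [
        AnnotationTable(term_id=t, term_name=t, category=category,
                        member_symbols=m & u, universe=u)
        for t, m in groups.items()
    ]


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------


def read_qpcr_plate(
    plate_path: str | os.PathLike,
    efficiencies_path: str | os.PathLike,
    reference_genes: set[str],
):
    """Long-format plate (gene, sample, group, replicate, CT) plus a
    two-column efficiency table (gene, efficiency as % or linear factor)."""
    from .qpcr import QPCRPlate, efficiency_to_linear

    records = pd.read_csv(plate_path, sep=SEP, dtype={"gene": str, "sample": str,
                                                      "group": str})
    eff = pd.read_csv(efficiencies_path, sep=SEP, dtype={"gene": str})
    eff_col = [c for c in eff.columns if c != "gene"][0]
    efficiencies = {
        g: efficiency_to_linear(float(v)) for g, v in zip(eff["gene"], eff[eff_col])
    }
    return QPCRPlate(
        records=records, efficiencies=efficiencies,
        reference_genes=set(reference_genes),
    )


def write_qpcr_plate(plate, plate_path, efficiencies_path) -> None:
    plate.records.to_csv(plate_path, sep=SEP, index=False, float_format="%.6f")
    pd.DataFrame(
        {"gene": list(plate.efficiencies),
         "efficiency": [plate.efficiencies[g] for g in plate.efficiencies]}
    ).to_csv(efficiencies_path, sep=SEP, index=False)
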