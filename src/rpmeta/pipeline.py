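"""End-to-end driver: simulate -> RP -> lists -> comparison -> signature.

Chains the whole analysis on a seeded multi-study simulation (or on
pre-existing matrices) and writes every intermediate as re-parseable
delimiter-separated text: per-study RP tables, strict and extended gene
lists, R-I and volcano plot data tables, the sample dendrogram (newick),
comparison matrices, the Venn-region table, the intersection signature,
and optional enrichment tables — plus a run log recording seeds,
permutation counts, and the probe count after every filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .enrichment import hypergeom_enrich
from .listbuild import (FilterConfig, GeneList, apply_cutoffs,
                        collapse_to_symbols, detection_filter,
                        resolve_direction_conflicts)
from .meta_compare import StudyListSet, comparison_matrix, intersect_signature
from .rankprod import RPConfig, cluster_samples, rp_analyze
from .synthetic import MultiStudyConfig, generate_multi_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; the seed reaches every stochastic stage."""

    simulation: MultiStudyConfig
    rp: RPConfig = field(default_factory=RPConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    out_dir: str | Path = "out"
    seed: int = 0
    gmt_path: str | Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.gmt_path is not None and not Path(self.gmt_path).exists():
            raise FileNotFoundError(f"gene-set file not found: {self.gmt_path}")


@dataclass
class PipelineOutput:
    """Handles on everything a run produced."""

    listset: StudyListSet
    signature: object
    out_dir: Path
    run_log: dict


def _plot_tables(result, out_dir: Path, study_name: str) -> None:
    """R-I (log-ratio vs log-product of group means) and volcano
    (log2 RP vs log2 FC) plot data."""
    t = result.table
    log_fc = np.log2(t["FC"].to_numpy())
    ri = pd.DataFrame(
        {
            "probe_id": t["probe_id"],
            "log2_ratio": t["mean_case"] - t["mean_control"],
            "log2_product": t["mean_case"] + t["mean_control"],
        }
    )
    volcano = pd.DataFrame(
        {
            "probe_id": t["probe_id"],
            "log2_FC": log_fc,
            "log2_RP_up": np.log2(t["RP_up"].to_numpy()),
            "log2_RP_down": np.log2(t["RP_down"].to_numpy()),
            "p_up": t["p_up"],
            "p_down": t["p_down"],
        }
    )
    ri.to_csv(out_dir / f"{study_name}.ri_plot.tsv", sep="\t", index=False,
              float_format="%.6g")
    volcano.to_csv(out_dir / f"{study_name}.volcano.tsv", sep="\t", index=False,
                   float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> PipelineOutput:
    """Run simulation, per-study RP analysis, list building, cross-study
    comparison and signature extraction; write all outputs under
    ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {
        "seed": config.seed,
        "n_permutations": config.rp.n_permutations,
        "stages": {},
    }

    stage = "simulate"
    try:
        sim = config.simulation
        sim = MultiStudyConfig(**{**sim.__dict__, "seed": config.seed})
        studies, truth = generate_multi_study(sim)
        run_log["stages"][stage] = {
            s.study_name: {"probes": s.n_probes} for s in studies
        }

        lists: dict[str, dict[str, GeneList]] = {}
        for study in studies:
            stage = f"rankprod[{study.study_name}]"
            rp_cfg = RPConfig(
                n_permutations=config.rp.n_permutations,
                seed=config.seed,
            )
            result = rp_analyze(study, rp_cfg)
            rio.write_rp_result(result, out_dir / f"{study.study_name}.rp.tsv")
            _plot_tables(result, out_dir, study.study_name)
            tree = cluster_samples(study)
            (out_dir / f"{study.study_name}.dendrogram.nwk").write_text(
                tree.to_newick() + "\n"
            )

            stage = f"listbuild[{study.study_name}]"
            counts = {"probes_in": result.n_genes}
            filtered = detection_filter(result, study, config.filters)
            counts["after_detection"] = filtered.n_genes
            pair = {}
            for direction in ("up", "down"):
                gl = apply_cutoffs(filtered, config.filters, direction)
                counts[f"after_cutoffs_{direction}"] = len(gl)
                pair[direction] = collapse_to_symbols(gl)
                counts[f"after_collapse_{direction}"] = len(pair[direction])
            pair["up"], pair["down"] = resolve_direction_conflicts(
                pair["up"], pair["down"]
            )
            for direction in ("up", "down"):
                rio.write_gene_list(
                    pair[direction],
                    out_dir / f"{study.study_name}.{direction}.list.tsv",
                )
            lists[study.study_name] = pair
            run_log["stages"][stage] = counts

        stage = "compare"
        listset = StudyListSet(lists=lists)
        for direction in ("up", "down"):
            cm = comparison_matrix(listset, direction).rounded()
            cm.shared_pct.to_csv(out_dir / f"shared_{direction}.tsv", sep="\t")
            cm.inverted_pct.to_csv(out_dir / f"inverted_{direction}.tsv", sep="\t")

        stage = "signature"
        signature = intersect_signature(listset)
        signature.membership.to_csv(
            out_dir / "signature.tsv", sep="\t", index=False, float_format="%.6g"
        )
        venn_rows = [
            {"direction": d, "region": "&".join(sorted(region)), "count": count}
            for d, regions in signature.venn_counts.items()
            for region, count in regions.items()
        ]
        pd.DataFrame(venn_rows).to_csv(out_dir / "venn.tsv", sep="\t", index=False)
        run_log["stages"][stage] = {
            "n_up": signature.n_up, "n_down": signature.n_down
        }

        if config.gmt_path is not None:
            stage = "enrichment"
            terms = rio.read_gmt(config.gmt_path)
            sig_symbols = set(signature.up_symbols) | set(signature.down_symbols)
            enr = hypergeom_enrich(sig_symbols, terms)
            enr.table.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False,
                             float_format="%.6g")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    run_log["truth"] = {
        name: {"n_up": len(up), "n_down": len(down)}
        for name, (up, down) in truth.per_study_truth.items()
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")
    return PipelineOutput(
        listset=listset, signature=signature, out_dir=out_dir, run_log=run_log
    )
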