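"""Rank Products differential expression with a permutation null.

The Rank Products (RP) statistic is a non-parametric test for two-group
differential expression designed for experiments with few replicates.  For
each of the k = n_case * n_control pairwise case/control sample comparisons,
genes are ranked by their expression log-ratio; a gene's RP is the geometric
mean of its k ranks.  Genes that are consistently near the top of every
pairwise ranking get a small RP.  Significance is assessed against a null in
which the order of all genes is random: B sets of k independent uniform
permutations of 1..N are drawn, their RP values computed, and the expected
number of false positives E_g at each observed RP estimated by counting null
RP values at least as extreme.  From E_g follow the permutation p-value
p_g = E_g / N and the percentage of false prediction pfp_g = E_g / rank_g,
RP's analogue of the FDR.

Both directions are always analysed: "up" ranks by probability of
up-regulation in cases, "down" by probability of down-regulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import rankdata

Direction = Literal["up", "down"]

CASE = "case"
CONTROL = "control"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """One study's normalized log2 expression matrix with group labels.

    Parameters
    ----------
    probe_ids
        Probe(set) identifiers, one per matrix row; unique.
    symbols
        Gene symbols parallel to ``probe_ids``; may repeat (several probesets
        can measure one gene) and may be empty strings for un-named probes.
    matrix
        Log2-scale intensities, probes x samples.  Normalization (quantile /
        RMA / lumi) is upstream of this package.
    group_labels
        Per-sample label, each ``"case"`` or ``"control"``.
    detection
        Optional probes x samples matrix of MAS5-like detection calls
        ("P"/"M"/"A").
    detection_p
        Optional probes x samples matrix of detection p-values.
    """

    probe_ids: list[str]
    symbols: list[str]
    matrix: np.ndarray
    group_labels: list[str]
    sample_ids: list[str] | None = None
    detection: np.ndarray | None = None
    detection_p: np.ndarray | None = None
    study_name: str = "study"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n_probes, n_samples = self.matrix.shape
        if len(self.probe_ids) != n_probes:
            raise ValueError(
                f"{len(self.probe_ids)} probe ids for {n_probes} matrix rows"
            )
        if len(self.symbols) != n_probes:
            raise ValueError("symbols must be parallel to probe_ids")
        if len(self.group_labels) != n_samples:
            raise ValueError(
                f"{len(self.group_labels)} group labels for {n_samples} samples"
            )
        bad = set(self.group_labels) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if len(set(self.probe_ids)) != n_probes:
            dup = pd.Index(self.probe_ids)
            dup = dup[dup.duplicated()].tolist()
            raise ValueError(f"duplicated probe ids: {dup[:5]}")
        for lbl in (CASE, CONTROL):
            if self.group_labels.count(lbl) < 1:
                raise ValueError(f"no {lbl} samples")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i+1}" for i in range(n_samples)]

    @property
    def n_probes(self) -> int:
        return self.matrix.shape[0]

    @property
    def case_idx(self) -> np.ndarray:
        return np.array([g == CASE for g in self.group_labels])

    @property
    def control_idx(self) -> np.ndarray:
        return np.array([g == CONTROL for g in self.group_labels])


@dataclass
class RPConfig:
    """Settings for the permutation null. B defaults to 1000 permutations.

    ``null_scheme`` selects how the B random-gene-order experiments are
    built.  ``"experiment"`` (default) randomizes the gene order within
    every array of the observed experiment and recomputes the pairwise rank
    matrix, preserving the dependence between pairwise comparisons that
    share a sample — this is what keeps the permutation p-values calibrated
    for the all-pairs scheme.  ``"independent"`` draws the k rank columns
    as independent uniform permutations (the idealised null of
    :func:`permutation_null`); it admits exact small-case enumeration but
    understates the RP spread when k > n_case + n_control - 1.
    """

    n_permutations: int = 1000
    seed: int = 0
    comparison_mode: str = "all_pairs"
    tie_rule: str = "average"
    null_scheme: Literal["experiment", "independent"] = "experiment"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.comparison_mode != "all_pairs":
            raise ValueError("only the all_pairs comparison scheme is supported")
        if self.tie_rule != "average":
            raise ValueError("only average tie ranks are supported")
        if self.null_scheme not in ("experiment", "independent"):
            raise ValueError(f"unknown null scheme {self.null_scheme!r}")


@dataclass
class RankProductResult:
    """Per-probe RP statistics for both directions plus fold changes.

    ``table`` has one row per probe with columns probe_id, symbol, FC,
    and per direction d: RP_d, rank_d, E_d, p_d, pfp_d.  FC is the
    linear-scale case/control fold change 2**(mean_case - mean_control).
    """

    table: pd.DataFrame
    n_genes: int
    k: int
    n_permutations: int
    seed: int
    study_name: str = "study"

    def direction_table(self, direction: Direction) -> pd.DataFrame:
        """Rows ordered by ascending RP rank for one direction."""
        d = direction
        cols = ["probe_id", "symbol", "FC", f"RP_{d}", f"rank_{d}", f"E_{d}",
                f"p_{d}", f"pfp_{d}"]
        return self.table[cols].sort_values(f"rank_{d}").reset_index(drop=True)


# ---------------------------------------------------------------------------
# rank matrix and RP statistic
# ---------------------------------------------------------------------------


def pairwise_rank_matrix(study: ExpressionStudy, direction: Direction) -> np.ndarray:
    """Rank genes within every case/control sample pair.

    Returns an N x k matrix (k = n_case * n_control).  For ``direction="up"``
    rank 1 is the most up-regulated gene in that pair (largest case - control
    log-ratio); for ``"down"`` rank 1 is the most down-regulated.  Ties get
    average ranks.
    """
    case = study.matrix[:, study.case_idx]
    control = study.matrix[:, study.control_idx]
    # N x (n_case*n_control) log-ratios, one column per sample pair
    ratios = (case[:, :, None] - control[:, None, :]).reshape(study.n_probes, -1)
    signed = -ratios if direction == "up" else ratios
    return rankdata(signed, method="average", axis=0)


def rank_product(rank_matrix: np.ndarray) -> np.ndarray:
    """Geometric mean of each gene's ranks, computed in log space."""
    rank_matrix = np.asarray(rank_matrix, dtype=float)
    if np.any(rank_matrix <= 0):
        raise ValueError("ranks must be positive")
    return np.exp(np.mean(np.log(rank_matrix), axis=1))


def _log_rp(rank_matrix: np.ndarray) -> np.ndarray:
    return np.mean(np.log(rank_matrix), axis=1)


def permutation_null(
    n_genes: int, k: int, config: RPConfig, *, log: bool = False
) -> np.ndarray:
    """Draw the RP null: B x N values from k random rank columns each.

    Under the null the order of genes in every pairwise comparison is
    random, so each of the B permutation rounds draws k independent uniform
    permutations of 1..N and computes the RP of every row.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    B = config.n_permutations
    rng = np.random.default_rng(config.seed)
    out = np.empty((B, n_genes))
    base = np.arange(1.0, n_genes + 1.0)
    # chunked to bound memory at ~chunk*k*N floats
    chunk = max(1, int(2_000_000 / max(1, k * n_genes)))
    row = 0
    while row < B:
        b = min(chunk, B - row)
        # argsort of uniforms gives uniform random permutations
        u = rng.random((b, k, n_genes))
        perms = base[np.argsort(np.argsort(u, axis=-1), axis=-1)]
        out[row:row + b] = np.mean(np.log(perms), axis=1)
        row += b
    return out if log else np.exp(out)


def experiment_permutation_null(
    study: ExpressionStudy, config: RPConfig
) -> np.ndarray:
    """B x N null log-RP values preserving the experiment's structure.

    Each permutation round randomizes the gene order independently within
    every array (sample) of the observed matrix and recomputes the
    all-pairs rank matrix, so pairwise comparisons that share a sample stay
    as correlated under the null as they are in the data.  By the up/down
    mirror symmetry of ranks the same null serves both directions.
    """
    rng = np.random.default_rng(config.seed)
    B = config.n_permutations
    N = study.n_probes
    case = study.matrix[:, study.case_idx]
    control = study.matrix[:, study.control_idx]
    n_case, n_control = case.shape[1], control.shape[1]
    out = np.empty((B, N))
    chunk = max(1, int(2_000_000 / max(1, n_case * n_control * N)))
    row = 0
    while row < B:
        b = min(chunk, B - row)
        # independent gene-order permutation per array, per round
        pc = np.empty((b, N, n_case))
        pt = np.empty((b, N, n_control))
        for i in range(b):
            for j in range(n_case):
                pc[i, :, j] = case[rng.permutation(N), j]
            for j in range(n_control):
                pt[i, :, j] = control[rng.permutation(N), j]
        ratios = (pc[:, :, :, None] - pt[:, :, None, :]).reshape(b, N, -1)
        ranks = rankdata(-ratios, method="average", axis=1)
        out[row:row + b] = np.mean(np.log(ranks), axis=2)
        row += b
    return out


def rp_analyze(study: ExpressionStudy, config: RPConfig | None = None) -> RankProductResult:
    """Full Rank Products analysis of one study, both directions.

    For each direction the expected number of false positives at each
    observed RP_g is E_g = #{null RP <= RP_g} / B, the p-value is E_g / N
    (floored at 1/(B*N): a permutation p of exactly 0 is an artifact), and
    pfp_g = E_g / rank_g.
    """
    config = config or RPConfig()
    N = study.n_probes
    case_mean = study.matrix[:, study.case_idx].mean(axis=1)
    control_mean = study.matrix[:, study.control_idx].mean(axis=1)
    fc = 2.0 ** (case_mean - control_mean)
    k = int(study.case_idx.sum()) * int(study.control_idx.sum())

    if config.null_scheme == "experiment":
        null_log = experiment_permutation_null(study, config)
    else:
        null_log = permutation_null(N, k, config, log=True)
    null_sorted = np.sort(null_log.ravel())
    B = config.n_permutations

    cols: dict[str, np.ndarray] = {
        "probe_id": np.asarray(study.probe_ids, dtype=object),
        "symbol": np.asarray(study.symbols, dtype=object),
        "FC": fc,
        "mean_case": case_mean,
        "mean_control": control_mean,
    }
    for direction in ("up", "down"):
        ranks = pairwise_rank_matrix(study, direction)  # type: ignore[arg-type]
        log_rp = _log_rp(ranks)
        order_rank = rankdata(log_rp, method="ordinal")
        # small numerical slack so exactly-tied null values count as <=
        e = np.searchsorted(null_sorted, log_rp * (1 + 1e-12) + 1e-12,
                            side="right") / B
        p = np.clip(e / N, 1.0 / (B * N), 1.0)
        pfp = e / order_rank
        cols[f"RP_{direction}"] = np.exp(log_rp)
        cols[f"rank_{direction}"] = order_rank.astype(int)
        cols[f"E_{direction}"] = e
        cols[f"p_{direction}"] = p
        cols[f"pfp_{direction}"] = pfp

    table = pd.DataFrame(cols)
    return RankProductResult(
        table=table, n_genes=N, k=k, n_permutations=B, seed=config.seed,
        study_name=study.study_name,
    )


# ---------------------------------------------------------------------------
# sample clustering QC
# ---------------------------------------------------------------------------


def cluster_samples(study: ExpressionStudy) -> "SampleTree":
    """UPGMA dendrogram of samples under centred-correlation distance.

    Distance between two samples is 1 - Pearson correlation of their
    (mean-centred) expression vectors; agglomeration is by average linkage.
    """
    X = study.matrix.T  # samples x probes
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to cluster")
    sds = X.std(axis=1)
    for i, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(
                f"sample {study.sample_ids[i]} is constant; "
                "correlation distance undefined"
            )
    centred = X - X.mean(axis=1, keepdims=True)
    corr = np.corrcoef(centred)
    dist = 1.0 - corr
    n = X.shape[0]
    condensed = dist[np.triu_indices(n, k=1)]
    Z = linkage(condensed, method="average")
    return SampleTree(Z, list(study.sample_ids or []))


@dataclass
class SampleTree:
    """Average-linkage sample dendrogram with newick export."""

    linkage_matrix: np.ndarray
    labels: list[str]

    def cut(self, n_clusters: int) -> np.ndarray:
        from scipy.cluster.hierarchy import fcluster

        return fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            inner = ",".join(walk(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{parent_height - node.dist:.6g}"

        body = ",".join(walk(c, tree.dist) for c in (tree.left, tree.right))
        return f"({body});"
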