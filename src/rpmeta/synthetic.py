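"""Synthetic multi-study expression data with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
two-group (case vs control) log2 expression matrix with i.i.d. Gaussian
noise, planted up-/down-regulated genes at a configurable log2 effect,
MAS5-like present/absent detection calls with per-cell detection p-values,
many-to-one probeset-to-symbol maps (1-3 probes per gene), several studies
whose true DE sets partially overlap concordantly or with inverted
direction, and qPCR plates following exponential amplification with CT
noise.  Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rankprod import CASE, CONTROL, ExpressionStudy


@dataclass
class SimulationConfig:
    """Design of one synthetic two-group study.

    Defaults mirror a small clinical microarray comparison: 5 case vs 5
    control samples, ~2-fold planted effects (1 log2 unit) against 0.25 log2
    units of noise, and 1-3 probesets per gene.
    """

    n_genes: int = 1000
    probe_multiplicity_probs: tuple[float, float, float] = (0.85, 0.12, 0.03)
    n_case: int = 5
    n_control: int = 5
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 2.0
    noise_sd_log2: float = 0.25
    n_up_true: int = 50
    n_down_true: int = 50
    effect_log2fc: float = 1.0
    present_prob_expressed: float = 0.95
    present_prob_unexpressed: float = 0.10
    seed: int = 0
    study_name: str = "sim"

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("sample counts must be positive")
        if self.n_up_true + self.n_down_true > self.n_genes:
            raise ValueError("more planted DE genes than genes")
        probs = (self.present_prob_expressed, self.present_prob_unexpressed)
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("detection probabilities must be in [0, 1]")
        if self.baseline_sd_log2 <= 0 or self.noise_sd_log2 < 0:
            raise ValueError("baseline sd must be > 0 and noise sd >= 0")
        if abs(sum(self.probe_multiplicity_probs) - 1.0) > 1e-9:
            raise ValueError("probe multiplicity probabilities must sum to 1")


@dataclass
class MultiStudyConfig:
    """Design of a set of studies with overlapping truth.

    ``shared_up_fraction`` / ``shared_down_fraction`` of each study's true
    sets form a concordant core common to all studies; ``inverted_fraction``
    of each non-reference study's planted genes are drawn from the reference
    study's truth with the opposite sign, emulating the inverted-expression
    phenomenon seen when comparing independent studies.  Study gene
    universes share a common platform core of ``platform_overlap_fraction``.
    """

    study_configs: list[SimulationConfig] = field(default_factory=list)
    shared_up_fraction: float = 0.3
    shared_down_fraction: float = 0.3
    inverted_fraction: float = 0.1
    platform_overlap_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.shared_up_fraction, self.shared_down_fraction,
                 self.inverted_fraction, self.platform_overlap_fraction)
        if not all(0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("fractions must be in [0, 1]")
        if self.shared_up_fraction + self.inverted_fraction > 1.0:
            raise ValueError("shared_up_fraction + inverted_fraction > 1")
        if self.shared_down_fraction + self.inverted_fraction > 1.0:
            raise ValueError("shared_down_fraction + inverted_fraction > 1")


@dataclass
class GroundTruth:
    """Planted regulation, overall and per study."""

    true_up: set[str]
    true_down: set[str]
    per_study_truth: dict[str, tuple[set[str], set[str]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.true_up & self.true_down:
            raise ValueError("a symbol cannot be planted in both directions")
        for name, (up, down) in self.per_study_truth.items():
            if up & down:
                raise ValueError(f"study {name}: up/down truth sets overlap")


def _symbols(n: int, prefix: str = "GENE") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_study(
    config: SimulationConfig,
    *,
    symbols: list[str] | None = None,
    up_symbols: set[str] | None = None,
    down_symbols: set[str] | None = None,
) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate one two-group study.

    Planted up genes have case mean = control mean + ``effect_log2fc`` on
    every one of their probes (down genes the negative).  Detection calls
    are Bernoulli per cell: probes whose baseline sits more than one
    baseline SD below the baseline mean are treated as unexpressed and use
    the lower present probability.  Present cells draw a detection p-value
    uniform on (0, 0.01), absent cells uniform on (0, 1).

    ``symbols`` / ``up_symbols`` / ``down_symbols`` let a multi-study
    driver impose the gene universe and the planted sets; by default they
    are generated from the config.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    if symbols is None:
        symbols = _symbols(G)
    if len(symbols) != G:
        raise ValueError("symbol universe size must equal n_genes")

    if up_symbols is None or down_symbols is None:
        order = rng.permutation(G)
        up_symbols = {symbols[i] for i in order[: config.n_up_true]}
        down_symbols = {
            symbols[i]
            for i in order[config.n_up_true: config.n_up_true + config.n_down_true]
        }
    if up_symbols & down_symbols:
        raise ValueError("up and down truth sets overlap")

    # 1-3 probes per gene to exercise symbol collapsing
    mult = rng.choice([1, 2, 3], size=G, p=list(config.probe_multiplicity_probs))
    probe_symbols: list[str] = []
    probe_ids: list[str] = []
    for g, m in enumerate(mult):
        for j in range(m):
            probe_symbols.append(symbols[g])
            probe_ids.append(f"{config.study_name}_p{g + 1}_{j + 1}")
    P = len(probe_ids)
    n = config.n_case + config.n_control

    baseline = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, size=P)
    effect = np.zeros(P)
    sym_arr = np.asarray(probe_symbols, dtype=object)
    effect[np.isin(sym_arr, list(up_symbols))] = config.effect_log2fc
    effect[np.isin(sym_arr, list(down_symbols))] = -config.effect_log2fc

    matrix = baseline[:, None] + rng.normal(0.0, config.noise_sd_log2, size=(P, n))
    matrix[:, : config.n_case] += effect[:, None]

    expressed = baseline >= config.baseline_mean_log2 - config.baseline_sd_log2
    p_present = np.where(
        expressed, config.present_prob_expressed, config.present_prob_unexpressed
    )
    present = rng.random((P, n)) < p_present[:, None]
    detection = np.where(present, "P", "A").astype(object)
    detection_p = np.where(
        present, rng.uniform(0.0, 0.01, size=(P, n)), rng.uniform(0.0, 1.0, size=(P, n))
    )

    labels = [CASE] * config.n_case + [CONTROL] * config.n_control
    sample_ids = [f"{config.study_name}_case{i+1}" for i in range(config.n_case)] + [
        f"{config.study_name}_ctrl{i+1}" for i in range(config.n_control)
    ]
    study = ExpressionStudy(
        probe_ids=probe_ids,
        symbols=probe_symbols,
        matrix=matrix,
        group_labels=labels,
        sample_ids=sample_ids,
        detection=detection,
        detection_p=detection_p,
        study_name=config.study_name,
    )
    truth = GroundTruth(
        true_up=set(up_symbols),
        true_down=set(down_symbols),
        per_study_truth={config.study_name: (set(up_symbols), set(down_symbols))},
    )
    return study, truth


def generate_multi_study(
    config: MultiStudyConfig,
) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Simulate several studies with partially overlapping planted truth.

    The first study config is the reference.  A concordant core of
    ``round(shared_fraction * n_true)`` symbols per direction is planted in
    every study; each non-reference study additionally inverts
    ``round(inverted_fraction * n_true)`` of the reference's genes (planted
    with opposite sign) and fills the remainder with study-specific genes.
    All shared and inverted genes live in the common platform core of the
    symbol universe.
    """
    if len(config.study_configs) < 2:
        raise ValueError("need at least 2 study configs")
    rng = np.random.default_rng(config.seed)
    ref = config.study_configs[0]
    G = ref.n_genes
    for sc in config.study_configs:
        if sc.n_genes != G:
            raise ValueError("all studies must use the same n_genes")

    n_core = int(round(config.platform_overlap_fraction * G))
    pool = _symbols(G + (G - n_core) * (len(config.study_configs) - 1))
    core = pool[:n_core]

    n_shared_up = int(round(config.shared_up_fraction * ref.n_up_true))
    n_shared_down = int(round(config.shared_down_fraction * ref.n_down_true))
    n_inv_up = int(round(config.inverted_fraction * ref.n_up_true))
    n_inv_down = int(round(config.inverted_fraction * ref.n_down_true))
    need = ref.n_up_true + ref.n_down_true
    if need > n_core:
        raise ValueError("platform core too small to hold the planted truth")

    core_perm = [core[i] for i in rng.permutation(n_core)]
    ref_up = core_perm[: ref.n_up_true]
    ref_down = core_perm[ref.n_up_true: need]
    shared_up = set(ref_up[:n_shared_up])
    shared_down = set(ref_down[:n_shared_down])
    # inverted genes come from the reference's non-shared remainder
    inv_from_up = ref_up[n_shared_up: n_shared_up + n_inv_up]
    inv_from_down = ref_down[n_shared_down: n_shared_down + n_inv_down]
    spare = [s for s in core_perm[need:]]

    studies: list[ExpressionStudy] = []
    per_study: dict[str, tuple[set[str], set[str]]] = {}
    spare_pos = 0
    extra_pos = n_core

    for idx, sc in enumerate(config.study_configs):
        name = sc.study_name if sc.study_name != "sim" else f"sim{idx + 1}"
        if idx == 0:
            universe = list(core) + pool[extra_pos: extra_pos + (G - n_core)]
            extra_pos += G - n_core
            up, down = set(ref_up), set(ref_down)
        else:
            universe = list(core) + pool[extra_pos: extra_pos + (G - n_core)]
            extra_pos += G - n_core
            up = set(shared_up) | set(inv_from_down)
            down = set(shared_down) | set(inv_from_up)
            # study-specific fill to reach the configured truth sizes
            while len(up) < sc.n_up_true:
                up.add(spare[spare_pos] if spare_pos < len(spare) else universe[-1])
                spare_pos += 1
            while len(down) < sc.n_down_true:
                down.add(spare[spare_pos] if spare_pos < len(spare) else universe[-2])
                spare_pos += 1
        sc_named = SimulationConfig(
            **{**sc.__dict__, "study_name": name,
               "seed": int(rng.integers(0, 2**31 - 1))}
        )
        study, _ = generate_study(
            sc_named, symbols=universe, up_symbols=up, down_symbols=down
        )
        studies.append(study)
        per_study[name] = (up, down)

    all_up = set().union(*(u for u, _ in per_study.values()))
    all_down = set().union(*(d for _, d in per_study.values()))
    truth = GroundTruth(
        true_up=all_up - all_down,
        true_down=all_down - all_up,
        per_study_truth=per_study,
    )
    return studies, truth


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------


def generate_qpcr_plate(
    genes: list[str],
    fold_changes: dict[str, float],
    efficiencies: dict[str, float],
    n_case: int,
    n_control: int,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
    reference_genes: tuple[str, ...] = ("ACTB", "GAPDH"),
    base_ct: float = 24.0,
    n_replicates: int = 3,
):
    """Simulate a relative-quantification qPCR plate.

    CT values follow exponential amplification, CT = base - log_E(amount),
    where the case-group template amount is scaled by the planted fold
    change; Gaussian CT noise is added per well and each (gene, sample)
    is measured in ``n_replicates`` technical replicates.  Reference genes
    must be included with fold change 1.
    """
    from .qpcr import QPCRPlate

    missing = [g for g in reference_genes if g not in genes]
    if missing:
        raise ValueError(f"reference genes missing from plate: {missing}")
    for g in reference_genes:
        if abs(fold_changes.get(g, 1.0) - 1.0) > 1e-12:
            raise ValueError(f"reference gene {g} must have fold change 1")
    for g, e in efficiencies.items():
        if not (1.0 < e <= 2.2):
            raise ValueError(f"efficiency for {g} must be in (1, 2.2]")

    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        E = efficiencies.get(gene, 2.0)
        fc = fold_changes.get(gene, 1.0)
        if fc <= 0:
            raise ValueError(f"fold change for {gene} must be positive")
        for grp, n in ((CASE, n_case), (CONTROL, n_control)):
            amount = fc if grp == CASE else 1.0
            ct_true = base_ct - np.log(amount) / np.log(E)
            for s in range(n):
                # per-sample biological wobble shared by replicates
                sample_shift = rng.normal(0.0, ct_noise_sd)
                for r in range(n_replicates):
                    ct = ct_true + sample_shift + rng.normal(0.0, ct_noise_sd)
                    rows.append(
                        (gene, f"{grp}{s + 1}", grp, r + 1, float(ct))
                    )
    records = pd.DataFrame(
        rows, columns=["gene", "sample", "group", "replicate", "CT"]
    )
    return QPCRPlate(
        records=records,
        efficiencies={g: efficiencies.get(g, 2.0) for g in genes},
        reference_genes=set(reference_genes),
    )
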