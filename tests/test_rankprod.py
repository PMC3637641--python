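"""Rank Products statistic, permutation null, pfp, and sample clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpmeta.rankprod import (RPConfig, cluster_samples, pairwise_rank_matrix,
                             permutation_null, rank_product, rp_analyze)
from tests.conftest import make_study


# ---------------------------------------------------------------------------
# pairwise rank matrix
# ---------------------------------------------------------------------------


def test_single_pair_most_upregulated_gene_ranks_first():
    study = make_study([[5.0, 1.0], [2.0, 1.5], [1.0, 3.0]], 1, 1)
    ranks = pairwise_rank_matrix(study, "up")
    assert ranks.shape == (3, 1)
    assert ranks[0, 0] == 1  # largest case-control ratio
    assert ranks[2, 0] == 3
    down = pairwise_rank_matrix(study, "down")
    assert down[2, 0] == 1


def test_rank_matrix_has_one_column_per_sample_pair():
    study = make_study(np.arange(12.0).reshape(3, 4), 2, 2)
    assert pairwise_rank_matrix(study, "up").shape == (3, 4)


def test_rank_matrix_matches_hand_enumeration_2v2():
    # values chosen so the gene ordering differs between the 4 pairs;
    # per pair (case_i - ctrl_j): g0: 3,1,-1,-3; g1: .5,2,.5,2; g2: 1,-1,3,1
    m = np.array(
        [
            [5.0, 1.0, 2.0, 4.0],
            [3.0, 3.0, 2.5, 1.0],
            [2.0, 4.0, 1.0, 3.0],
        ]
    )
    study = make_study(m, 2, 2)
    ranks = pairwise_rank_matrix(study, "up")
    # pairs in order (case0,ctrl0),(case0,ctrl1),(case1,ctrl0),(case1,ctrl1)
    expected = np.array(
        [
            [1.0, 2.0, 3.0, 3.0],
            [3.0, 1.0, 2.0, 1.0],
            [2.0, 3.0, 1.0, 2.0],
        ]
    )
    np.testing.assert_array_equal(ranks, expected)


def test_constant_matrix_gives_all_average_ranks():
    study = make_study(np.ones((4, 2)), 1, 1)
    ranks = pairwise_rank_matrix(study, "up")
    np.testing.assert_array_equal(ranks, np.full((4, 1), 2.5))


# ---------------------------------------------------------------------------
# RP statistic
# ---------------------------------------------------------------------------


def test_rank_product_top_gene_and_geometric_mean():
    assert rank_product(np.array([[1.0, 1.0, 1.0]]))[0] == pytest.approx(1.0)
    assert rank_product(np.array([[2.0, 8.0]]))[0] == pytest.approx(4.0)


def test_rank_product_rejects_nonpositive_ranks():
    with pytest.raises(ValueError):
        rank_product(np.array([[0.0, 2.0]]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_rank_product_equals_direct_product_then_root(seed):
    rng = np.random.default_rng(seed)
    ranks = rng.integers(1, 6, size=(5, 3)).astype(float)
    direct = np.prod(ranks, axis=1) ** (1.0 / 3.0)
    np.testing.assert_allclose(rank_product(ranks), direct, atol=1e-12)


# ---------------------------------------------------------------------------
# permutation null vs exhaustive enumeration
# ---------------------------------------------------------------------------


def exact_null_rp_distribution(n, k):
    """All RP values of one fixed gene over the (n!)^k equally likely
    combinations of k independent rank columns."""
    values = []
    for cols in itertools.product(itertools.permutations(range(1, n + 1)), repeat=k):
        values.append(np.prod([c[0] for c in cols]) ** (1.0 / k))
    return np.array(values)


def test_null_n2_k1_two_equal_outcomes():
    null = permutation_null(2, 1, RPConfig(n_permutations=4000, seed=3))
    vals, counts = np.unique(null[:, 0], return_counts=True)
    np.testing.assert_allclose(vals, [1.0, 2.0])
    # each outcome has probability 1/2; 3 sigma binomial band
    se = np.sqrt(0.25 / 4000)
    assert abs(counts[0] / 4000 - 0.5) < 3 * se


def test_null_same_seed_is_identical():
    a = permutation_null(5, 2, RPConfig(n_permutations=50, seed=9))
    b = permutation_null(5, 2, RPConfig(n_permutations=50, seed=9))
    np.testing.assert_array_equal(a, b)


@pytest.mark.parametrize("n,k", [(3, 2), (4, 2), (4, 1), (2, 2)])
def test_null_matches_exhaustive_enumeration(n, k):
    """P(RP <= x) from permutation sampling converges to the exact
    enumeration over all (n!)^k rank-column combinations."""
    exact = exact_null_rp_distribution(n, k)
    B = 10_000
    null = permutation_null(n, k, RPConfig(n_permutations=B, seed=17))
    sample = null[:, 0]
    for x in np.unique(exact):
        p_exact = np.mean(exact <= x + 1e-9)
        p_hat = np.mean(sample <= x + 1e-9)
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert abs(p_hat - p_exact) <= 3 * se + 1e-12, (x, p_hat, p_exact)


def test_null_p_rp_le_1_is_one_ninth_for_n3_k2():
    null = permutation_null(3, 2, RPConfig(n_permutations=10_000, seed=23))
    p_hat = np.mean(null[:, 0] <= 1.0 + 1e-9)
    se = np.sqrt((1 / 9) * (8 / 9) / 10_000)
    assert abs(p_hat - 1 / 9) < 3 * se


def test_null_rejects_bad_sizes():
    with pytest.raises(ValueError):
        permutation_null(1, 1, RPConfig())
    with pytest.raises(ValueError):
        RPConfig(n_permutations=0)


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------


def test_noise_free_top_gene_ranks_first_with_minimal_pfp():
    m = np.tile([[8.0], [5.0], [5.0], [5.0]], (1, 6)).astype(float)
    m[0, :3] += 3.0  # strongest up-regulation
    m[1, :3] += 1.0
    study = make_study(m, 3, 3)
    res = rp_analyze(study, RPConfig(n_permutations=100, seed=1))
    top = res.direction_table("up").iloc[0]
    assert top["probe_id"] == "p0"
    assert top["rank_up"] == 1
    assert top["pfp_up"] == res.table["pfp_up"].min()


def test_pfp_times_rank_equals_E_and_p_is_E_over_N(planted_study):
    study, _ = planted_study
    res = rp_analyze(study, RPConfig(n_permutations=100, seed=2))
    t = res.table
    for d in ("up", "down"):
        np.testing.assert_allclose(
            t[f"pfp_{d}"] * t[f"rank_{d}"], t[f"E_{d}"], atol=1e-12
        )
        expected_p = np.clip(t[f"E_{d}"] / res.n_genes,
                             1.0 / (100 * res.n_genes), 1.0)
        np.testing.assert_allclose(t[f"p_{d}"], expected_p, atol=1e-12)
        # E is non-decreasing in RP
        order = np.argsort(t[f"RP_{d}"].to_numpy())
        assert np.all(np.diff(t[f"E_{d}"].to_numpy()[order]) >= -1e-12)


def test_swapping_groups_exchanges_directions():
    """Swapping case/control labels turns the up analysis into the down
    analysis: statistics exchange exactly, and p-values exchange exactly
    under the independent null (whose draw depends only on N, k, seed)."""
    rng = np.random.default_rng(4)
    m = rng.normal(8, 1, size=(30, 6))
    a = make_study(m, 3, 3)
    b = make_study(np.hstack([m[:, 3:], m[:, :3]]), 3, 3)
    cfg = RPConfig(n_permutations=200, seed=5, null_scheme="independent")
    ra, rb = rp_analyze(a, cfg), rp_analyze(b, cfg)
    np.testing.assert_allclose(ra.table["RP_up"], rb.table["RP_down"], atol=1e-12)
    np.testing.assert_allclose(ra.table["p_up"], rb.table["p_down"], atol=1e-12)
    np.testing.assert_allclose(ra.table["FC"] * rb.table["FC"], 1.0, atol=1e-12)
    # the default experiment-structure null exchanges the deterministic parts
    dcfg = RPConfig(n_permutations=50, seed=5)
    da, db = rp_analyze(a, dcfg), rp_analyze(b, dcfg)
    np.testing.assert_allclose(da.table["RP_up"], db.table["RP_down"], atol=1e-12)
    np.testing.assert_array_equal(da.table["rank_up"], db.table["rank_down"])


def test_null_type_one_error_close_to_nominal():
    """With no planted effect, ~5% of genes reach p <= 0.05 per direction."""
    from rpmeta.synthetic import SimulationConfig, generate_study

    cfg = SimulationConfig(n_genes=1000, probe_multiplicity_probs=(1.0, 0.0, 0.0),
                           n_up_true=0, n_down_true=0, effect_log2fc=0.0,
                           noise_sd_log2=0.25, seed=31)
    study, _ = generate_study(cfg)
    res = rp_analyze(study, RPConfig(n_permutations=200, seed=32))
    se = np.sqrt(0.05 * 0.95 / 1000)
    for d in ("up", "down"):
        frac = float((res.table[f"p_{d}"] <= 0.05).mean())
        assert abs(frac - 0.05) < 3 * se, (d, frac)


def test_p_values_uniform_under_exchangeable_null():
    """KS distance of null RP p-values from uniform < 0.05 (N=1000, B=1000)."""
    from rpmeta.synthetic import SimulationConfig, generate_study

    cfg = SimulationConfig(n_genes=1000, probe_multiplicity_probs=(1.0, 0.0, 0.0),
                           n_up_true=0, n_down_true=0, effect_log2fc=0.0,
                           seed=41)
    study, _ = generate_study(cfg)
    res = rp_analyze(study, RPConfig(n_permutations=1000, seed=42))
    for d in ("up", "down"):
        p = np.sort(res.table[f"p_{d}"].to_numpy())
        n = len(p)
        grid = np.arange(1, n + 1) / n
        ks = max(np.max(np.abs(grid - p)), np.max(np.abs(p - (grid - 1 / n))))
        assert ks < 0.05, (d, ks)


def auroc(scores_pos, scores_neg):
    """Probability a positive outscores a negative (rank-sum identity)."""
    from scipy.stats import rankdata

    all_scores = np.concatenate([scores_pos, scores_neg])
    ranks = rankdata(all_scores)
    n1, n0 = len(scores_pos), len(scores_neg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return u / (n1 * n0)


def test_planted_up_genes_recovered_with_high_auroc():
    """RP up-ranking separates planted 2-fold up genes (AUROC >= 0.95)."""
    from rpmeta.synthetic import SimulationConfig, generate_study

    cfg = SimulationConfig(n_genes=1000, probe_multiplicity_probs=(1.0, 0.0, 0.0),
                           n_up_true=100, n_down_true=0, effect_log2fc=1.0,
                           noise_sd_log2=0.25, seed=51)
    study, truth = generate_study(cfg)
    res = rp_analyze(study, RPConfig(n_permutations=100, seed=52))
    is_up = np.array([s in truth.true_up for s in res.table["symbol"]])
    score = -res.table["rank_up"].to_numpy()  # better rank = higher score
    assert auroc(score[is_up], score[~is_up]) >= 0.95


# ---------------------------------------------------------------------------
# sample clustering
# ---------------------------------------------------------------------------


def test_identical_samples_merge_first_at_zero_distance():
    rng = np.random.default_rng(6)
    base = rng.normal(8, 1, size=50)
    m = np.column_stack([base, base, base + rng.normal(0, 2, 50),
                         base + rng.normal(0, 2, 50)])
    study = make_study(m, 2, 2)
    tree = cluster_samples(study)
    first = tree.linkage_matrix[0]
    assert {int(first[0]), int(first[1])} == {0, 1}
    assert first[2] == pytest.approx(0.0, abs=1e-12)


def test_three_sample_merge_heights_match_hand_computation():
    m = np.array(
        [[1.0, 2.0, 5.0],
         [2.0, 1.0, 4.0],
         [3.0, 4.0, 3.0],
         [4.0, 3.0, 8.0]]
    )
    study = make_study(m, 2, 1)
    corr = np.corrcoef(m.T)
    d01, d02, d12 = 1 - corr[0, 1], 1 - corr[0, 2], 1 - corr[1, 2]
    first = min(d01, d02, d12)
    # average linkage: remaining sample joins at the mean of its two distances
    others = sorted([d01, d02, d12])
    second = (others[1] + others[2]) / 2
    heights = cluster_samples(study).merge_heights()
    np.testing.assert_allclose(heights, [first, second], atol=1e-12)


def test_separated_groups_recovered_by_two_cluster_cut():
    from rpmeta.synthetic import SimulationConfig, generate_study

    cfg = SimulationConfig(n_genes=300, n_up_true=60, n_down_true=60,
                           effect_log2fc=2.0, noise_sd_log2=0.1, seed=61)
    study, _ = generate_study(cfg)
    assign = cluster_samples(study).cut(2)
    labels = np.array(study.group_labels)
    case_clusters = set(assign[labels == "case"])
    ctrl_clusters = set(assign[labels == "control"])
    assert len(case_clusters) == 1 and len(ctrl_clusters) == 1
    assert case_clusters != ctrl_clusters


def test_constant_sample_is_rejected_by_name():
    m = np.array([[1.0, 2.0, 3.0], [1.0, 5.0, 4.0], [1.0, 3.0, 9.0]])
    study = make_study(m, 2, 1)
    with pytest.raises(ValueError, match="s1"):
        cluster_samples(study)


def test_newick_round_trips_all_labels():
    rng = np.random.default_rng(7)
    study = make_study(rng.normal(size=(20, 5)), 3, 2)
    nwk = cluster_samples(study).to_newick()
    assert nwk.endswith(";")
    for s in study.sample_ids:
        assert s in nwk
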