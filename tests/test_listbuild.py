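"""Detection filtering, cutoffs, length targeting, symbol collapsing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpmeta.listbuild import (FilterConfig, GeneList, apply_cutoffs,
                              collapse_to_symbols, detection_filter,
                              normalize_symbol, resolve_direction_conflicts,
                              size_targeted_list)
from rpmeta.rankprod import RPConfig, rp_analyze
from rpmeta.synthetic import SimulationConfig, generate_study
from tests.conftest import make_gene_list


@pytest.fixture(scope="module")
def analysed():
    cfg = SimulationConfig(
        n_genes=300, n_up_true=30, n_down_true=30, effect_log2fc=1.5,
        noise_sd_log2=0.25, present_prob_unexpressed=0.05, seed=21,
    )
    study, truth = generate_study(cfg)
    result = rp_analyze(study, RPConfig(n_permutations=100, seed=22))
    return study, truth, result


# ---------------------------------------------------------------------------
# detection filter
# ---------------------------------------------------------------------------


def test_detection_filter_extremes(analysed):
    study, _, result = analysed
    # force one probe all-absent, one all-present
    det = np.asarray(study.detection).copy()
    det[0, :] = "A"
    det[1, :] = "P"
    study2 = study.__class__(
        probe_ids=study.probe_ids, symbols=study.symbols, matrix=study.matrix,
        group_labels=study.group_labels, sample_ids=study.sample_ids,
        detection=det, detection_p=study.detection_p,
        study_name=study.study_name,
    )
    cfg = FilterConfig(detection_mode="fraction_present", detection_threshold=0.2)
    out = detection_filter(result, study2, cfg)
    assert study.probe_ids[0] not in set(out.table["probe_id"])
    assert study.probe_ids[1] in set(out.table["probe_id"])


def test_detection_filter_count_matches_recount(analysed):
    study, _, result = analysed
    cfg = FilterConfig(detection_mode="fraction_present", detection_threshold=0.2)
    out = detection_filter(result, study, cfg)
    recount = int(((np.asarray(study.detection) == "P").mean(axis=1) > 0.2).sum())
    assert out.n_genes == recount == len(out.table)


def test_detection_p_dialect_matches_recount(analysed):
    study, _, result = analysed
    cfg = FilterConfig(detection_mode="fraction_detected_p",
                       detection_threshold=0.1, detection_p=0.01)
    out = detection_filter(result, study, cfg)
    recount = int(((study.detection_p < 0.01).mean(axis=1) > 0.1).sum())
    assert out.n_genes == recount


def test_detection_filter_without_data_errors(analysed):
    study, _, result = analysed
    bare = study.__class__(
        probe_ids=study.probe_ids, symbols=study.symbols, matrix=study.matrix,
        group_labels=study.group_labels,
    )
    with pytest.raises(ValueError, match="detection"):
        detection_filter(result, bare, FilterConfig())


# ---------------------------------------------------------------------------
# cutoffs
# ---------------------------------------------------------------------------


def test_no_cutoffs_returns_full_ranked_list(analysed):
    _, _, result = analysed
    gl = apply_cutoffs(result, FilterConfig(p_max=1.0, pfp_max=1.0), "up")
    assert len(gl) == result.n_genes
    assert list(gl.entries["rank"]) == list(range(1, result.n_genes + 1))


def test_surviving_entries_satisfy_thresholds_on_recheck(analysed):
    _, _, result = analysed
    cfg = FilterConfig(p_max=1e-4, pfp_max=0.05)
    for d in ("up", "down"):
        gl = apply_cutoffs(result, cfg, d)
        assert len(gl) > 0
        assert (gl.entries["p"] <= 1e-4).all()
        assert (gl.entries["pfp"] <= 0.05).all()


def test_fc_cutoff_is_directional(analysed):
    _, _, result = analysed
    cfg = FilterConfig(p_max=1.0, pfp_max=1.0, fc_min=2.0)
    up = apply_cutoffs(result, cfg, "up")
    down = apply_cutoffs(result, cfg, "down")
    assert (up.entries["FC"] >= 2.0).all()
    assert (down.entries["FC"] <= 0.5).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    p1=st.floats(1e-6, 1.0), p2=st.floats(1e-6, 1.0),
    q1=st.floats(0.0, 1.0), q2=st.floats(0.0, 1.0),
)
def test_tightening_thresholds_is_monotone(analysed, p1, p2, q1, q2):
    _, _, result = analysed
    loose = FilterConfig(p_max=max(p1, p2), pfp_max=max(q1, q2))
    tight = FilterConfig(p_max=min(p1, p2), pfp_max=min(q1, q2))
    for d in ("up", "down"):
        big = set(apply_cutoffs(result, loose, d).entries["probe_id"])
        small = set(apply_cutoffs(result, tight, d).entries["probe_id"])
        assert small <= big


def test_detection_and_cutoff_order_commutes(analysed):
    study, _, result = analysed
    cfg = FilterConfig(p_max=0.01, pfp_max=0.2)
    a = apply_cutoffs(detection_filter(result, study, cfg), cfg, "up")
    b_pre = apply_cutoffs(result, cfg, "up")
    # both are row-subset predicates, so order does not matter
    filtered = detection_filter(result, study, cfg)
    surviving = set(filtered.table["probe_id"])
    b = b_pre.entries[b_pre.entries["probe_id"].isin(surviving)]
    assert list(a.entries["probe_id"]) == list(b["probe_id"])


# ---------------------------------------------------------------------------
# size-targeted lists
# ---------------------------------------------------------------------------


def test_target_length_zero_rejected(analysed):
    _, _, result = analysed
    with pytest.raises(ValueError):
        size_targeted_list(result, "up", 0)


def test_full_qualifying_target_equals_pfp_cutoff_alone(analysed):
    _, _, result = analysed
    qualifying = apply_cutoffs(result, FilterConfig(p_max=1.0, pfp_max=1.0), "up")
    n_q = int((qualifying.entries["pfp"] < 0.05).sum())
    gl = size_targeted_list(result, "up", n_q)
    assert len(gl) == n_q
    assert (gl.entries["pfp"] < 0.05).all()


def test_size_target_keeps_best_ranked(analysed):
    _, _, result = analysed
    gl = size_targeted_list(result, "up", 10)
    assert len(gl) <= 10
    full = size_targeted_list(result, "up", 10_000)
    excluded = full.entries.iloc[len(gl):]
    if len(excluded):
        assert excluded["rank"].min() > gl.entries["rank"].max()


# ---------------------------------------------------------------------------
# symbol collapsing
# ---------------------------------------------------------------------------


def test_collapse_noop_for_unique_symbols():
    gl = make_gene_list(["A", "B", "C"], collapsed=False)
    out = collapse_to_symbols(gl)
    assert out.collapsed
    pd.testing.assert_frame_equal(out.entries, gl.entries)


def test_collapse_keeps_best_ranked_probe_statistics():
    entries = pd.DataFrame(
        {
            "rank": [3, 40],
            "probe_id": ["pA1", "pA2"],
            "symbol": ["X", "X"],
            "FC": [2.5, 1.9],
            "p": [1e-5, 1e-3],
            "pfp": [0.001, 0.04],
        }
    )
    gl = GeneList(study_name="S", direction="up", entries=entries,
                  universe_size=100)
    out = collapse_to_symbols(gl)
    assert len(out) == 1
    assert out.entries.iloc[0]["rank"] == 3
    assert out.entries.iloc[0]["FC"] == 2.5


def test_collapse_length_equals_distinct_mapped_symbols(analysed):
    _, _, result = analysed
    gl = apply_cutoffs(result, FilterConfig(p_max=1.0, pfp_max=1.0), "up")
    out = collapse_to_symbols(gl)
    assert len(out) == gl.entries["symbol"].nunique()
    assert not out.entries["symbol"].duplicated().any()
    # every output row's statistics exist verbatim in the input
    merged = out.entries.merge(gl.entries, on=["probe_id", "symbol"],
                               suffixes=("", "_in"))
    assert len(merged) == len(out)
    np.testing.assert_array_equal(merged["p"], merged["p_in"])


def test_collapse_drops_unmapped_probes():
    gl = make_gene_list(["A", "B", "C"], collapsed=False)
    out = collapse_to_symbols(gl, mapping={"S_0": "A", "S_2": "C"})
    assert list(out.entries["symbol"]) == ["A", "C"]


def test_symbol_normalization():
    assert normalize_symbol("  c9orf3 ") == "C9ORF3"


def test_direction_conflicts_resolved_by_better_rank():
    up = make_gene_list(["A", "B"], direction="up")
    down = make_gene_list(["B", "C"], direction="down")
    # B ranks 2 in up, 1 in down -> stays in down
    new_up, new_down = resolve_direction_conflicts(up, down)
    assert new_up.symbols == {"A"}
    assert new_down.symbols == {"B", "C"}
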