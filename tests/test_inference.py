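"""Paired t-maps, Benjamini–Hochberg q-values, P-P data, and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dxarfa import (
    AnalysisConfig,
    bh_qvalues,
    compare_area_proportions,
    paired_t_map,
    pp_plot,
    summarize_remodeling,
)
from dxarfa.inference import PixelTestMap, RemodelingSummary
from dxarfa.registration import RegisteredCohortStack, ShapeTemplate


def _stack(base, follow, template_mask=None):
    """Assemble a 2-visit stack from (subjects, rows, cols) arrays."""
    base = np.asarray(base, float)
    follow = np.asarray(follow, float)
    s, h, w = base.shape
    values = np.stack([base, follow], axis=1).astype(np.float32)
    avail = np.ones((s, 2, h, w), dtype=bool)
    mask = np.ones((h, w), bool) if template_mask is None else template_mask
    lm = np.random.default_rng(0).uniform(0, 10, (16, 2))
    lmc = lm - lm.mean(0)
    template = ShapeTemplate(
        mean_landmarks=lmc / np.linalg.norm(lmc),
        grid_landmarks_mm=lm,
        grid_shape=(h, w),
        pixel_spacing_mm=1.0,
        template_bone_mask=mask,
    )
    return RegisteredCohortStack(
        values=values,
        availability=avail,
        subject_ids=tuple(f"S{i}" for i in range(s)),
        visit_months=(0.0, 24.0),
        group_id="g",
        template=template,
    )


def _test_map_from_p(p, pct=None):
    p = np.asarray(p, float).reshape(1, -1)
    n = p.size
    pct = np.ones_like(p) if pct is None else np.asarray(pct, float).reshape(1, -1)
    return PixelTestMap(
        t_stat=np.zeros_like(p),
        df=np.full_like(p, 9.0),
        p_value=p,
        n_pixel=np.full(p.shape, 10),
        pct_change=pct,
        defined=np.isfinite(p),
        followup_month=24.0,
        baseline_month=0.0,
    )


def _brute_force_bh(p, alpha):
    """Independent step-up oracle: scan all N candidate thresholds."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    k_sel = 0
    for i in range(1, n + 1):
        if p[order[i - 1]] <= alpha * i / n:
            k_sel = i
    selected = np.zeros(n, bool)
    selected[order[:k_sel]] = True
    return selected


# ---------------------------------------------------------------------------
# paired t


def test_paired_t_matches_closed_form_example():
    """Differences (1,2,3,4,5) give t = 4.2426, df = 4, p = 0.01324."""
    base = np.zeros((5, 1, 1))
    follow = np.array([1.0, 2, 3, 4, 5]).reshape(5, 1, 1)
    base += 1.0
    follow += 1.0
    tm = paired_t_map(_stack(base, follow), 24.0)
    assert tm.N == 1
    assert tm.t_stat[0, 0] == pytest.approx(4.2426, abs=1e-4)
    assert tm.df[0, 0] == 4
    assert tm.p_value[0, 0] == pytest.approx(0.01324, abs=1e-5)


def test_paired_t_matches_scipy_on_random_pixels(rng):
    from scipy import stats

    base = rng.uniform(0.5, 3.0, (8, 4, 5))
    follow = base + rng.normal(0, 0.1, base.shape)
    tm = paired_t_map(_stack(base, follow), 24.0)
    ref = stats.ttest_rel(follow, base, axis=0)
    # the stack stores BMD as float32, so agreement is to single precision
    assert np.allclose(tm.t_stat, ref.statistic, atol=1e-4)
    assert np.allclose(tm.p_value, ref.pvalue, atol=1e-6)


def test_identical_visits_have_zero_variance_everywhere():
    base = np.full((6, 3, 3), 1.5)
    tm = paired_t_map(_stack(base, base.copy()), 24.0)
    assert tm.N == 0
    assert tm.n_sd_zero_excluded == 9


def test_pixels_below_subject_minimum_are_excluded(rng):
    base = rng.uniform(1, 2, (6, 2, 2))
    follow = base + rng.normal(0, 0.1, base.shape)
    stack = _stack(base, follow)
    stack.availability[3:, :, 0, 0] = False  # only 3 subjects at pixel (0,0)
    tm = paired_t_map(stack, 24.0, AnalysisConfig(min_subjects_per_pixel=5))
    assert not tm.defined[0, 0]
    assert tm.N == 3


def test_pct_change_is_mean_subject_relative_change(rng):
    base = rng.uniform(1, 2, (6, 1, 1))
    follow = base * 1.1
    tm = paired_t_map(_stack(base, follow), 24.0)
    assert tm.pct_change[0, 0] == pytest.approx(10.0, abs=1e-4)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg


def test_bh_worked_example():
    """p = (.01,.02,.03,.04), N = 4 → q = (.04,.04,.04,.04), all significant."""
    qm = bh_qvalues(_test_map_from_p([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
    assert np.allclose(qm.q_value[0], 0.04)
    assert qm.significant.all()


def test_bh_all_p_one_selects_nothing():
    qm = bh_qvalues(_test_map_from_p([1.0] * 8), alpha=0.9999)
    assert np.allclose(qm.q_value[0], 1.0)
    assert not qm.significant.any()


def test_bh_selection_equals_brute_force_step_up_oracle():
    rng = np.random.default_rng(20170413)
    for _ in range(1000):
        n = int(rng.integers(1, 1001))
        mix = rng.random(n)
        p = np.where(rng.random(n) < 0.3, mix * 0.01, mix)
        alpha = float(rng.uniform(0.01, 0.2))
        qm = bh_qvalues(_test_map_from_p(p), alpha=alpha)
        assert np.array_equal(qm.significant[0], _brute_force_bh(p, alpha))


def test_bh_matches_statsmodels_qvalues(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.random(500)
    qm = bh_qvalues(_test_map_from_p(p), alpha=0.05)
    reject, q_ref, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
    assert np.allclose(qm.q_value[0], q_ref, atol=1e-12)
    assert np.array_equal(qm.significant[0], reject)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_bh_q_dominates_p_and_selections_nest_in_alpha(p):
    tm = _test_map_from_p(p)
    qm1 = bh_qvalues(tm, alpha=0.02)
    qm2 = bh_qvalues(tm, alpha=0.10)
    assert (qm1.q_value[0] >= np.asarray(p) - 1e-12).all()
    assert (qm1.significant <= qm2.significant).all()  # nested selections
    # monotone along the sorted-p order
    order = np.argsort(p, kind="stable")
    assert (np.diff(qm1.q_value[0][order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# P-P data


def test_pp_plot_crossing_matches_worked_example():
    ppd = pp_plot(_test_map_from_p([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
    assert ppd.crossing_p == pytest.approx(0.04)
    assert np.allclose(ppd.uniform_quantiles, np.arange(1, 5) / 5)


def test_pp_plot_no_crossing_for_large_p():
    ppd = pp_plot(_test_map_from_p([0.5, 0.7, 0.9]), alpha=0.05)
    assert ppd.crossing_p is None


def test_pp_plot_uniform_sample_close_to_diagonal(rng):
    p = rng.random(10000)
    ppd = pp_plot(_test_map_from_p(p), alpha=0.05)
    dev = np.abs(ppd.sorted_p - ppd.uniform_quantiles).max()
    assert dev < 0.03


# ---------------------------------------------------------------------------
# summaries and group comparison


def _summary_inputs(p, pct, mask=None):
    tm = _test_map_from_p(p, pct)
    qm = bh_qvalues(tm, alpha=0.05)
    h, w = tm.p_value.shape
    lm = np.random.default_rng(0).uniform(0, 10, (16, 2))
    lmc = lm - lm.mean(0)
    template = ShapeTemplate(
        mean_landmarks=lmc / np.linalg.norm(lmc),
        grid_landmarks_mm=lm,
        grid_shape=(h, w),
        pixel_spacing_mm=1.0,
        template_bone_mask=np.ones((h, w), bool) if mask is None else mask,
    )
    return qm, tm, template


def test_summary_empty_significant_set_reports_zeros():
    qm, tm, template = _summary_inputs([0.5, 0.8, 0.9, 0.7], [1, -1, 2, -2])
    s = summarize_remodeling(qm, tm, template)
    assert s.area_total_pct == 0.0
    assert s.mean_change_increase_pct == 0.0 and s.mean_change_decrease_pct == 0.0


def test_summary_saturated_increase():
    qm, tm, template = _summary_inputs([1e-6] * 5, [3, 4, 5, 6, 7])
    s = summarize_remodeling(qm, tm, template)
    assert s.area_total_pct == 100.0
    assert s.area_increase_pct == 100.0
    assert s.mean_change_increase_pct == pytest.approx(5.0)


def test_summary_partition_adds_up(rng):
    p = rng.random(50) * 0.2
    pct = rng.normal(0, 5, 50)
    qm, tm, template = _summary_inputs(p, pct)
    s = summarize_remodeling(qm, tm, template)
    assert s.area_increase_pct + s.area_decrease_pct == pytest.approx(s.area_total_pct)


def _summary_counts(sig, total):
    return RemodelingSummary(
        area_total_pct=100 * sig / total,
        area_increase_pct=0.0,
        area_decrease_pct=0.0,
        mean_change_increase_pct=0.0,
        mean_change_decrease_pct=0.0,
        n_template_pixels=total,
        n_sig_total=sig,
        n_sig_increase=0,
        n_sig_decrease=0,
    )


def test_chi_squared_worked_example():
    """Table [[20, 80], [40, 60]] → chi2 = 9.5238, p = 0.00203."""
    a = _summary_counts(20, 100)
    b = _summary_counts(40, 100)
    stat, p = compare_area_proportions(a, b, direction="total")
    assert stat == pytest.approx(9.5238, abs=1e-3)
    assert p == pytest.approx(0.00203, abs=2e-5)


def test_chi_squared_identical_groups_is_zero():
    a = _summary_counts(20, 100)
    stat, p = compare_area_proportions(a, _summary_counts(20, 100))
    assert stat == 0.0 and p == 1.0


def test_chi_squared_symmetric_under_group_swap():
    a = _summary_counts(123, 5000)
    b = _summary_counts(456, 6000)
    assert compare_area_proportions(a, b)[0] == pytest.approx(
        compare_area_proportions(b, a)[0]
    )


def test_chi_squared_three_group_comparison_has_df_2():
    from scipy import stats

    sums = [_summary_counts(s, 1000) for s in (50, 80, 120)]
    stat, p = compare_area_proportions(*sums, direction="total")
    assert p == pytest.approx(float(stats.chi2.sf(stat, 2)))
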