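"""Pixel-wise change inference with false-discovery-rate control.

At every template bone pixel with enough contributing subjects, the BMD
change from baseline to a follow-up visit is tested with a paired t-test.
The resulting p-value map is corrected for multiple testing with the
Benjamini–Hochberg step-up procedure: sort the N p-values increasingly,
form the raw quantities q̃(i) = p(i)·N/i, and enforce monotonicity with a
cumulative minimum from the largest index downward,

    q(i) = min_{j ≥ i} p(j)·N/j,   capped at 1.

q(i) is then the minimum FDR level α at which pixel (i) would be selected,
and the set {q ≤ α} equals the classic BH step-up selection at level α.

Summaries use the standard remodeling-table layout: the areal size of the
significant set as a percentage of all template bone pixels, split by the
sign of the mean percent change, with the mean percent change over each
subset; areal proportions are compared between prosthesis designs with a
Pearson chi-squared test (no continuity correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import AnalysisConfig, InputError
from .registration import RegisteredCohortStack, ShapeTemplate

__all__ = [
    "PixelTestMap",
    "QValueMap",
    "PPPlotData",
    "RemodelingSummary",
    "paired_t_map",
    "bh_qvalues",
    "pp_plot",
    "summarize_remodeling",
    "compare_area_proportions",
]

logger = logging.getLogger(__name__)


@dataclass
class PixelTestMap:
    """Per-pixel paired-t results on the template grid.

    Arrays are NaN (or 0 for ``n_pixel``) where the pixel was not tested;
    ``defined`` flags the N pixels that enter multiple-testing correction.
    """

    t_stat: np.ndarray
    df: np.ndarray
    p_value: np.ndarray
    n_pixel: np.ndarray
    pct_change: np.ndarray
    defined: np.ndarray
    followup_month: float
    baseline_month: float
    n_sd_zero_excluded: int = 0

    @property
    def N(self) -> int:
        return int(self.defined.sum())


@dataclass
class QValueMap:
    """Benjamini–Hochberg q-values and the significant-pixel selection."""

    q_value: np.ndarray
    raw_q: np.ndarray
    significant: np.ndarray
    alpha: float


@dataclass
class PPPlotData:
    """Sorted p-values against uniform quantiles, plus the BH threshold.

    ``crossing_p`` is the largest p(i) with p(i) ≤ α·i/N (the BH step-up
    threshold), or None when nothing is selected.
    """

    sorted_p: np.ndarray
    uniform_quantiles: np.ndarray
    bh_line_slope: float
    crossing_p: float | None


@dataclass
class RemodelingSummary:
    """Areal size and mean magnitude of significant BMD change.

    Areas are percentages of all template bone pixels; mean changes are the
    means of pixel-level percent change over the significant increase /
    decrease subsets (reported as 0.0 when the subset is empty, mirroring
    the usual table convention for empty subsets).
    """

    area_total_pct: float
    area_increase_pct: float
    area_decrease_pct: float
    mean_change_increase_pct: float
    mean_change_decrease_pct: float
    n_template_pixels: int
    n_sig_total: int
    n_sig_increase: int
    n_sig_decrease: int
    group_id: str = ""
    followup_month: float = float("nan")


def paired_t_map(
    stack: RegisteredCohortStack,
    followup_month: float,
    config: AnalysisConfig | None = None,
) -> PixelTestMap:
    """Pixel-wise paired t-test of follow-up vs baseline BMD.

    A pixel is tested when at least ``config.min_subjects_per_pixel``
    subjects are available at both the baseline and the follow-up visit;
    pixels whose paired differences have zero standard deviation are
    excluded from N (logged).  ``pct_change`` is the mean over subjects of
    (follow-up − baseline)/baseline × 100.
    """
    config = (config or AnalysisConfig()).validate()
    jb = stack.visit_index(config.baseline_visit)
    jf = stack.visit_index(followup_month)
    if jb == jf:
        raise InputError("follow-up visit equals the baseline visit")

    base = stack.values[:, jb].astype(float)
    follow = stack.values[:, jf].astype(float)
    avail = stack.availability[:, jb] & stack.availability[:, jf]

    d = np.where(avail, follow - base, 0.0)
    n = avail.sum(axis=0)
    n_safe = np.maximum(n, 1)
    mean_d = d.sum(axis=0) / n_safe
    ss = (np.where(avail, (d - mean_d) ** 2, 0.0)).sum(axis=0)
    sd_d = np.sqrt(ss / np.maximum(n - 1, 1))
    ok_base = avail & (base > 0)
    rel = np.where(ok_base, (follow - base) / np.where(base > 0, base, 1.0), 0.0)
    n_rel = ok_base.sum(axis=0)
    pct = np.where(n_rel > 0, rel.sum(axis=0) / np.maximum(n_rel, 1) * 100.0, np.nan)

    enough = n >= config.min_subjects_per_pixel
    sd_pos = sd_d > 0
    defined = enough & sd_pos
    n_sd_zero = int((enough & ~sd_pos).sum())
    if n_sd_zero:
        logger.info(
            "%d pixels excluded from N: zero-variance paired differences",
            n_sd_zero,
        )

    t = np.full(mean_d.shape, np.nan)
    p = np.full(mean_d.shape, np.nan)
    df = np.where(defined, n - 1, 0).astype(float)
    t[defined] = mean_d[defined] / (sd_d[defined] / np.sqrt(n[defined]))
    p[defined] = 2.0 * stats.t.sf(np.abs(t[defined]), df[defined])
    pct = np.where(enough, pct, np.nan)
    return PixelTestMap(
        t_stat=t,
        df=df,
        p_value=p,
        n_pixel=n,
        pct_change=pct,
        defined=defined,
        followup_month=float(followup_month),
        baseline_month=float(config.baseline_visit),
        n_sd_zero_excluded=n_sd_zero,
    )


def bh_qvalues(test_map: PixelTestMap, alpha: float = 0.05) -> QValueMap:
    """Map p-values to Benjamini–Hochberg q-values and select {q ≤ α}.

    Raw q̃(i) = p(i)·N/i along the increasing sort; the monotone q is the
    cumulative minimum from the largest index downward, capped at 1.  Ties
    in p receive the same monotone q.  The selected set equals the classic
    BH step-up set at level α.
    """
    shape = test_map.p_value.shape
    q = np.full(shape, np.nan)
    raw_q = np.full(shape, np.nan)
    significant = np.zeros(shape, dtype=bool)
    idx = np.flatnonzero(test_map.defined)
    n = idx.size
    if n == 0:
        return QValueMap(q_value=q, raw_q=raw_q, significant=significant, alpha=alpha)
    p = test_map.p_value.ravel()[idx]
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, n + 1)
    raw = p[order] * n / ranks
    mono = np.minimum.accumulate(raw[::-1])[::-1]
    mono = np.minimum(mono, 1.0)
    q_flat = np.empty(n)
    q_flat[order] = mono
    raw_flat = np.empty(n)
    raw_flat[order] = np.minimum(raw, 1.0)
    q.ravel()[idx] = q_flat
    raw_q.ravel()[idx] = raw_flat
    sig_flat = q_flat <= alpha
    significant.ravel()[idx] = sig_flat
    return QValueMap(q_value=q, raw_q=raw_q, significant=significant, alpha=alpha)


def pp_plot(test_map: PixelTestMap, alpha: float = 0.05) -> PPPlotData:
    """P-P diagnostic data: sorted p-values against uniform i/(N+1) quantiles.

    Under the global null the sorted p-values follow the identity diagonal;
    pixels below the slope-α line (p(i) ≤ α·i/N) are the BH selection.
    """
    p = np.sort(test_map.p_value[test_map.defined])
    n = p.size
    if n == 0:
        raise InputError("no defined p-values to plot")
    uq = np.arange(1, n + 1) / (n + 1)
    below = p <= alpha * np.arange(1, n + 1) / n
    crossing = float(p[np.nonzero(below)[0][-1]]) if below.any() else None
    return PPPlotData(
        sorted_p=p, uniform_quantiles=uq, bh_line_slope=alpha, crossing_p=crossing
    )


def summarize_remodeling(
    qmap: QValueMap,
    test_map: PixelTestMap,
    template: ShapeTemplate,
) -> RemodelingSummary:
    """Areal size (% of template bone pixels) and mean magnitude of change.

    The denominator is the full template bone mask ("all pixels in the
    template"); significant pixels split into increase/decrease by the sign
    of their mean percent change.  Empty subsets report 0.0 area and 0.0
    mean change.
    """
    if template.template_bone_mask is None:
        raise InputError("template has no bone mask")
    if qmap.significant.shape != template.template_bone_mask.shape:
        raise InputError("q-map and template grids differ")
    n_all = int(template.template_bone_mask.sum())
    sig = qmap.significant
    pct = test_map.pct_change
    inc = sig & (pct > 0)
    dec = sig & (pct < 0)
    n_sig = int(sig.sum())
    n_inc = int(inc.sum())
    n_dec = int(dec.sum())

    def area(k: int) -> float:
        return 100.0 * k / n_all if n_all else 0.0

    return RemodelingSummary(
        area_total_pct=area(n_sig),
        area_increase_pct=area(n_inc),
        area_decrease_pct=area(n_dec),
        mean_change_increase_pct=float(pct[inc].mean()) if n_inc else 0.0,
        mean_change_decrease_pct=float(pct[dec].mean()) if n_dec else 0.0,
        n_template_pixels=n_all,
        n_sig_total=n_sig,
        n_sig_increase=n_inc,
        n_sig_decrease=n_dec,
        group_id=template.group_id,
        followup_month=test_map.followup_month,
    )


def compare_area_proportions(
    *summaries: RemodelingSummary, direction: str = "total"
) -> tuple[float, float]:
    """Pearson chi-squared comparison of significant areal proportions.

    Builds the k×2 table of (significant, non-significant) template pixel
    counts across the k groups and returns (statistic, p) with df = k−1 and
    no continuity correction.  A warning is logged when any expected cell
    count falls below 1 (the result is still returned).
    """
    if len(summaries) == 1 and isinstance(summaries[0], (list, tuple)):
        summaries = tuple(summaries[0])
    if len(summaries) < 2:
        raise InputError("need at least two summaries to compare")
    key = {
        "total": "n_sig_total",
        "increase": "n_sig_increase",
        "decrease": "n_sig_decrease",
    }
    if direction not in key:
        raise InputError(f"direction must be one of {sorted(key)}")
    table = np.array(
        [
            [getattr(s, key[direction]), s.n_template_pixels - getattr(s, key[direction])]
            for s in summaries
        ],
        dtype=float,
    )
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if (expected < 1).any():
        logger.warning(
            "chi-squared comparison has expected cell counts below 1; "
            "result may be unreliable"
        )
    if np.all(table[:, 0] == table[0, 0]) and np.all(table[:, 1] == table[0, 1]):
        # identical groups: statistic exactly 0 without 0/0 worries
        return 0.0, 1.0
    stat = float(((table - expected) ** 2 / expected).sum())
    df = len(summaries) - 1
    return stat, float(stats.chi2.sf(stat, df))
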