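"""Detection and quantification of unfolding/refolding transitions in
force-extension sweeps, plus single-tether validation.

Detection is residual-based.  Along an elastic branch the measured extension
and force move together, ``dx = C dF`` with ``C`` the local tether
compliance (both are driven by the advancing trap separation), so the
per-sample residual ``r = dx - C dF`` sits at zero on branches regardless of
their curvature.  At a rip the tether gains (unfolding) or loses (refolding)
slack, and ``r`` spikes by the extension offset between the two branches at
matched force — the physically meaningful rip size, which is what a running
elastic-baseline fit measures.  The local compliance is estimated from
rolling medians of the increments; residuals beyond ``slope_k`` median
absolute deviations (with an absolute floor tied to ``min_size``) mark
candidates, adjacent candidates are merged, and the branch-offset jump is
kept only if it reaches the minimum size (default 10 nm).  Forces are
quantified as the average over a short window immediately before the jump
onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .trace import ForceExtensionTrace, TraceError

__all__ = [
    "Transition",
    "detect_transitions",
    "transition_force",
    "validate_tether",
]

logger = logging.getLogger(__name__)


@dataclass
class Transition:
    """One detected rip.

    ``index_range = (onset, end)``: the jump spans samples onset..end
    (inclusive); the branch before the rip ends at ``onset`` and the branch
    after begins at ``end + 1``.
    """

    direction: str  # unfold | refold
    index_range: tuple[int, int]
    extension_jump: float  # nm, absolute size
    force_before: float  # pN (filled by transition_force)
    preceding_branch_id: int
    following_branch_id: int


def _local_compliance(
    x: np.ndarray,
    f: np.ndarray,
    lag: int = 8,
    window: int = 25,
    c_max: float = 60.0,
    df_floor: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided rolling estimates of the branch compliance dx/dF (nm/pN).

    Per-sample force increments are noise-dominated on soft branches, so
    the ratio uses lag-``lag`` differences (enough force travel per
    difference to be measurable) smoothed by a rolling median.  ``past[i]``
    uses data at or before sample i, ``future[i]`` data at or after it:
    one-sided windows matter because an estimate straddling a rip mixes two
    branches with different loading rates.
    """
    n = x.size
    dxl = x[lag:] - x[:-lag]
    dfl = f[lag:] - f[:-lag]
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(np.abs(dfl) > df_floor, dxl / np.where(dfl == 0, 1.0, dfl), c_max)
    c = np.clip(c, 0.0, c_max)
    # window > 3*lag so the (up to ``lag``) ratios straddling a rip are
    # always a median minority
    mc = median_filter(c, size=window, mode="nearest")
    h = window // 2
    # mc[j] summarizes samples ~[j-h, j+h+lag]
    past = mc[np.clip(np.arange(n) - lag - h, 0, mc.size - 1)]
    future = mc[np.clip(np.arange(n) + h, 0, mc.size - 1)]
    return past, future


def _side_means(v: np.ndarray, m: int, gap: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """pre[i] = mean(v[i-m+1..i]), post[i] = mean(v[i+1+gap..i+m+gap])
    (nan-padded ends).  The gap lets the post window clear a jump that is
    smeared over a few samples by decimation."""
    n = v.size
    c = np.concatenate(([0.0], np.cumsum(v)))
    pre = np.full(n, np.nan)
    post = np.full(n, np.nan)
    i = np.arange(m - 1, n)
    pre[i] = (c[i + 1] - c[i + 1 - m]) / m
    j = np.arange(0, n - m - gap)
    post[j] = (c[j + 1 + gap + m] - c[j + 1 + gap]) / m
    return pre, post


def detect_transitions(
    trace: ForceExtensionTrace,
    min_size: float = 10.0,
    slope_k: float = 5.0,
    merge_gap: int = 3,
    window: float = 0.05,
    side_window: int = 4,
    size_window: int = 12,
    min_force: float = 2.5,
) -> list[Transition]:
    """Detect rips whose branch-offset size reaches ``min_size`` nm.

    A sliding matched statistic ``J[i]`` estimates the branch offset for a
    putative rip between samples i and i+1: the difference of
    ``side_window``-sample means of extension on either side, compliance-
    corrected to matched force.  ``J`` beyond ``slope_k`` rolling MADs of
    its local baseline (with an absolute floor tied to ``min_size``) flags
    candidates; candidates are reduced by non-maximum suppression, the jump
    span follows the monotone force excursion, and the size is re-measured
    with per-branch compliances estimated away from the jump.  Jumps below
    ``min_size`` are never reported; candidates below ``min_force`` pN are
    ignored (slack tether, no meaningful elastic reference).
    """
    if len(trace) < 50:
        raise TraceError("trace too short for transition detection (< 50 samples)")
    m = side_window
    n = len(trace)
    x = trace.extension
    f = trace.force
    f_med = median_filter(f, size=3, mode="nearest")
    dx = np.diff(x)
    df = np.diff(f_med)
    comp_past, comp_future = _local_compliance(x, f)
    # symmetric gain for candidate scoring (stable); the reported size uses
    # the post-branch compliance, the correct gain for extrapolating the
    # post branch back to the pre-rip force
    comp_mid = 0.5 * (comp_past + comp_future)
    comp_full = comp_mid
    r = dx - comp_mid[:-1] * df  # single-increment residual, to localize jumps

    gap = 2  # clears jumps smeared over a couple of samples by decimation
    x_pre, x_post = _side_means(x, m, gap)
    f_pre, f_post = _side_means(f, m, gap)
    j_stat = (x_post - x_pre) - comp_full * (f_post - f_pre)
    j_stat[~np.isfinite(j_stat)] = 0.0
    # local baseline and noise scale: residual noise grows with compliance
    # (soft tether at low force), so the threshold adapts; the absolute
    # floor keeps smooth elastic curvature on noiseless sweeps out
    floor = 0.5 * min_size
    # wide windows: a train of rips ~10 samples apart must stay a median
    # minority, or the baseline swallows the plateaus it should sit under
    base = median_filter(j_stat, size=121, mode="nearest")
    dev = j_stat - base
    # clip before the rolling MAD so rip plateaus cannot inflate the local
    # noise estimate and mask a neighbouring smaller rip
    mad = median_filter(np.minimum(np.abs(dev), floor), size=161, mode="nearest")
    # capped just below min_size: in rip-dense regions the rolling MAD reads
    # unmodeled structure as noise, but any excursion of rip amplitude
    # deserves a look — the independent size gate does the rejecting
    thr = np.clip(slope_k * mad, floor, 0.95 * min_size)

    cand = np.abs(dev) > thr
    # the rolling estimators pad at the sweep ends, where a single outlier
    # ratio can masquerade as structure; no physical rip lives there (the
    # sweep turnaround is either fully unfolded or slack)
    edge = 25
    cand[:edge] = False
    cand[n - edge :] = False
    cand &= f_med >= min_force
    idx = np.flatnonzero(cand)
    # non-maximum suppression at the plateau scale: one peak per rip, but
    # rips ~10 samples apart stay distinct
    radius = 2 * m + gap - 2
    peaks: list[int] = []
    for i in idx[np.argsort(-np.abs(dev[idx]))]:
        if all(abs(int(i) - p) > radius for p in peaks):
            peaks.append(int(i))

    spans = []
    for peak in sorted(peaks):
        sign = 1 if dev[peak] > 0 else -1
        a, e = _jump_span(r, f_med, peak, sign, m)
        spans.append((sign, a, e))
    transitions: list[Transition] = []
    for k, (sign, a, e) in enumerate(spans):
        # size windows as long as the flanking branches allow (averaging
        # down the force noise sharpens the min_size gate), offset from the
        # jump by a few samples so the gate is statistically independent of
        # the correlated noise excursion that may have triggered the
        # candidate: a real rip's branch offset persists, a noise blip's
        # does not
        pre_limit = spans[k - 1][2] if k > 0 else 0
        post_limit = spans[k + 1][1] if k + 1 < len(spans) else n - 1
        skip_pre = int(np.clip(a - pre_limit - 4, 0, 5))
        skip_post = int(np.clip(post_limit - e - 3, 0, 5))
        m_pre = int(np.clip(a - skip_pre - pre_limit, 2, size_window))
        m_post = int(np.clip(post_limit - (e + skip_post) + 1, 2, size_window))
        f_star = float(f_med[a])  # evaluate the offset at the flip force
        jump = _offset_at_matched_force(
            x, f, comp_past, comp_future, a - skip_pre, e + skip_post,
            m_pre, m_post, f_star,
        )
        if sign * jump < min_size:
            continue
        transitions.append(
            Transition(
                direction=_direction(trace.sweep, sign),
                index_range=(a, e),
                extension_jump=abs(float(jump)),
                force_before=float("nan"),
                preceding_branch_id=-1,
                following_branch_id=-1,
            )
        )
    merged: list[Transition] = []
    for t in transitions:
        if merged and t.index_range[0] - merged[-1].index_range[1] < merge_gap:
            continue  # overlapping claim of the same jump
        merged.append(t)
    for i, t in enumerate(merged):
        t.preceding_branch_id = i
        t.following_branch_id = i + 1
        t.force_before = transition_force(trace, t, window=window)
    return merged


def _jump_span(
    r: np.ndarray, f_med: np.ndarray, peak: int, sign: int, m: int
) -> tuple[int, int]:
    """Localize the jump around a candidate peak: onset ``a`` is the sample
    with the largest signed single-increment residual, and the span extends
    forward while the (median-filtered) force keeps moving in the rip
    direction (drop for unfold, rise for refold).  Returns (a, e): sample
    ``a`` is the last pre-rip sample, ``e`` the first post-rip sample."""
    lo = max(peak - m, 0)
    hi = min(peak + m, r.size - 1)
    a = lo + int(np.argmax(sign * r[lo : hi + 1]))
    e = a + 1
    while e + 1 < f_med.size and e < a + 2 * m and sign * (f_med[e] - f_med[e + 1]) > 0.05:
        e += 1
    return a, e


def _offset_at_matched_force(
    x: np.ndarray,
    f: np.ndarray,
    comp_past: np.ndarray,
    comp_future: np.ndarray,
    a: int,
    e: int,
    m_pre: int,
    m_post: int,
    f_star: float,
) -> float:
    """Extension offset between the branches flanking the jump span,
    evaluated at the flip force ``f_star``: each side's window mean is
    extrapolated to ``f_star`` along its own branch (one-sided compliance),
    because the offset itself grows with force and must be quoted at the
    force where the rip happened."""
    n = x.size
    pre = slice(max(a - m_pre + 1, 0), a + 1)
    post = slice(e, min(e + m_post, n))
    x_pre = float(np.mean(x[pre]))
    f_pre = float(np.mean(f[pre]))
    x_post = float(np.mean(x[post]))
    f_post = float(np.mean(f[post]))
    c_pre = float(comp_past[min(a, comp_past.size - 1)])
    c_post = float(comp_future[min(e, comp_future.size - 1)])
    x_pre_star = x_pre + c_pre * (f_star - f_pre)
    x_post_star = x_post + c_post * (f_star - f_post)
    return x_post_star - x_pre_star






def _direction(sweep: str, sign: int) -> str:
    # extension gain = unfolding, loss = refolding, on either sweep
    return "unfold" if sign > 0 else "refold"


def transition_force(
    trace: ForceExtensionTrace, transition: Transition, window: float = 0.05
) -> float:
    """Average force (pN) over the ``window`` seconds immediately preceding
    the jump onset.

    The onset sample itself is excluded (it may straddle the flip after
    decimation).  If the preceding branch is shorter than the window the
    average shrinks to the available samples, with a logged warning.
    """
    onset = transition.index_range[0]
    dt = float(np.median(np.diff(trace.time)))
    n_want = max(int(round(window / dt)), 1)
    start = onset - n_want
    if start < 0:
        logger.warning(
            "transition_force window shrunk from %d to %d samples (onset %d)",
            n_want, onset, onset,
        )
        start = 0
    if onset == 0:
        return float(trace.force[0])
    return float(np.mean(trace.force[start:onset]))


def validate_tether(
    stretch: ForceExtensionTrace,
    relax: ForceExtensionTrace | None,
    total_dlc: float,
    expected_dlc: float,
    tolerance: float = 0.3,
    rupture_floor: float = 0.3,
) -> str:
    """Single-tether validity check: ``valid``, ``multi_tether`` or ``broken``.

    The cumulative unfolded length must not exceed the construct's expected
    contour gain by more than ``tolerance`` (a doubled total is the signature
    of two parallel tethers), and any rupture (force collapsing to ~0 and
    staying there) must not occur: a trace that ruptures mid-sweep is
    flagged broken.
    """
    f = stretch.force
    loaded = np.flatnonzero(f > 2.0)
    if loaded.size:
        after = f[loaded[0]:]
        low = np.flatnonzero(after < rupture_floor)
        if low.size and float(np.mean(after[low[0]:])) < 2 * rupture_floor:
            return "broken"
    if total_dlc > expected_dlc * (1.0 + tolerance):
        return "multi_tether"
    return "valid"
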