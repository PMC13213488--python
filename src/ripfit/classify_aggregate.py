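"""Cycle classification, contour-length-change distributions and summary
statistics.

A stretching cycle is *full* when its total contour-length change recovers
at least 90% of the construct's expected gain; *misfolded* when it falls
short despite high applied force (>= 20 pN), i.e. part of the chain could
not be unfolded; *locked* when neither stretch nor relax shows any
transition of at least 10 nm while the tether is still valid (the molecule
persists unfolded).  Thresholds are exposed as arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .wlc_fitting import CycleResult

__all__ = [
    "DistributionSummary",
    "BoxStats",
    "classify_cycle",
    "delta_lc_distribution",
    "zero_peak_mass",
    "welch_t_test",
    "box_stats",
]


@dataclass
class DistributionSummary:
    bin_edges: np.ndarray
    counts: np.ndarray
    peak_location: float
    peak_sd: float
    fraction_by_class: dict[str, float]
    n: int


class BoxStats(NamedTuple):
    """Box-chart order statistics: whiskers at the 10th/90th percentiles,
    box spanning the interquartile range, line at the median, square at the
    mean."""

    p10: float
    p25: float
    median: float
    mean: float
    p75: float
    p90: float


def classify_cycle(
    result: CycleResult,
    expected_dlc: float,
    relax_result: CycleResult | None = None,
    full_fraction: float = 0.9,
    high_force: float = 20.0,
    min_jump: float = 10.0,
) -> str | None:
    """Label one cycle: ``full`` / ``misfolded`` / ``locked``.

    ``expected_dlc`` is the construct's complete-unfolding contour gain
    (~200 nm), not any per-cycle value.  Invalid tethers are excluded
    (returns None).  Locked takes precedence: a locked cycle is never
    counted as misfolded.
    """
    if result.tether_status != "valid":
        return None
    stretch_jumps = [t for t in result.transitions if t.extension_jump >= min_jump]
    relax_jumps = (
        [t for t in relax_result.transitions if t.extension_jump >= min_jump]
        if relax_result is not None
        else []
    )
    if not stretch_jumps and not relax_jumps:
        return "locked"
    if result.total_dlc >= full_fraction * expected_dlc:
        return "full"
    if result.max_force >= high_force:
        return "misfolded"
    return "indeterminate"


def delta_lc_distribution(
    cycles: Sequence[CycleResult],
    bin_width: float = 5.0,
    min_cycles: int = 10,
) -> DistributionSummary:
    """Histogram of per-cycle total ΔLc with the dominant peak located by a
    local quadratic fit around the modal bin.

    Locked cycles contribute ΔLc = 0 (they produce a separate zero peak).
    """
    if len(cycles) == 0:
        raise ValueError("no cycles to summarize")
    if len(cycles) < min_cycles:
        raise ValueError(f"need at least {min_cycles} classified cycles, got {len(cycles)}")
    totals = np.array(
        [0.0 if c.label == "locked" else c.total_dlc for c in cycles], dtype=float
    )
    lo = min(0.0, totals.min())
    hi = totals.max() + bin_width
    edges = np.arange(np.floor(lo / bin_width) * bin_width, hi + bin_width, bin_width)
    counts, edges = np.histogram(totals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = _quadratic_peak(centers, counts)
    near = totals[np.abs(totals - peak) <= 1.5 * bin_width]
    peak_sd = float(np.std(near)) if near.size > 1 else 0.0
    labels = [c.label for c in cycles if c.label is not None]
    frac = {
        lab: labels.count(lab) / len(labels) for lab in sorted(set(labels))
    } if labels else {}
    return DistributionSummary(
        bin_edges=edges,
        counts=counts,
        peak_location=float(peak),
        peak_sd=peak_sd,
        fraction_by_class=frac,
        n=len(cycles),
    )


def _quadratic_peak(centers: np.ndarray, counts: np.ndarray) -> float:
    # modal bin picked on lightly smoothed counts so a one-bin noise spike
    # off the main mass cannot claim the peak; the vertex uses raw counts
    if len(counts) >= 3:
        smooth = np.convolve(counts, [0.25, 0.5, 0.25], mode="same")
    else:
        smooth = counts
    i = int(np.argmax(smooth))
    if i == 0 or i == len(counts) - 1:
        return float(centers[i])
    y0, y1, y2 = counts[i - 1], counts[i], counts[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(centers[i])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    return float(centers[i] + shift * (centers[1] - centers[0]))


def zero_peak_mass(
    cycles: Sequence[CycleResult], expected_dlc: float, zero_fraction: float = 0.1
) -> float:
    """Fraction of cycles sitting in the zero-ΔLc peak (total contour change
    below ``zero_fraction`` of the expected full gain); locked cycles count
    as zero."""
    if len(cycles) == 0:
        raise ValueError("no cycles")
    totals = np.array(
        [0.0 if c.label == "locked" else c.total_dlc for c in cycles], dtype=float
    )
    return float(np.mean(np.abs(totals) < zero_fraction * expected_dlc))


def welch_t_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample t-test assuming unequal variances (Welch), two-sided, with
    Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both samples have zero variance; t is undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def box_stats(sample) -> BoxStats:
    """Order statistics with the box-chart convention (10/25/50/75/90th
    percentiles by linear interpolation, plus the mean)."""
    a = np.asarray(sample, dtype=float)
    if a.size < 5:
        raise ValueError("need n >= 5 for box statistics")
    p10, p25, med, p75, p90 = np.percentile(a, [10, 25, 50, 75, 90], method="linear")
    return BoxStats(
        p10=float(p10), p25=float(p25), median=float(med),
        mean=float(np.mean(a)), p75=float(p75), p90=float(p90),
    )
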