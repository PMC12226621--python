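"""Registration evaluation: mean projection error, success rates,
equal-count capture-range histograms, and reader-preference tallying.

The mean projection error (MPE) projects the eight corners of the CTA
volume's bounding box onto the detector under the reference pose and the
estimated pose and averages the pixel distances; it is the package's single
accuracy number.  Capture-range analysis sorts many (before, after)
registrations by their initial MPE into equal-count bins and tracks the
per-bin median of the final MPE: the left edge of the first bin whose
median exceeds the success level — with no later recovery — is the capture
range of the method.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .geometry import CArmGeometry, VolumeGrid
from .render import project_points
from .se3 import RigidTransform

__all__ = [
    "CaptureRangeRecord",
    "PreferenceRecord",
    "CaptureRangeBin",
    "PreferenceTally",
    "mpe",
    "success_rate",
    "capture_range_histogram",
    "divergence_point",
    "tally_preferences",
    "signed_rank_test",
]


@dataclass(frozen=True)
class CaptureRangeRecord:
    mpe_before: float
    mpe_after: float
    case_id: str = ""

    def __post_init__(self):
        if self.mpe_before < 0 or self.mpe_after < 0:
            raise ValueError("MPE values must be non-negative")


@dataclass(frozen=True)
class PreferenceRecord:
    """One blind two-way comparison, scored 1 (left definitely better)
    through 5 (right definitely better); 3 is a tie."""

    left_method: str
    right_method: str
    score: int

    def __post_init__(self):
        if self.score not in (1, 2, 3, 4, 5):
            raise ValueError("score must be an integer 1-5")


@dataclass(frozen=True)
class CaptureRangeBin:
    lo: float
    hi: float
    median_after: float
    count: int


def mpe(
    t_ref: RigidTransform,
    t_reg: RigidTransform,
    volume: VolumeGrid,
    geom: CArmGeometry,
    unit: str = "px",
    points: np.ndarray | None = None,
) -> float:
    """Mean detector distance of the volume's 8 bounding-box corners
    projected under the reference vs. the estimated pose.

    ``unit`` is ``"px"`` (default) or ``"mm"`` (pixels times the detector
    pixel spacing).  ``points`` overrides the corner fiducials with an
    explicit (N, 3) world-mm list.  Points landing at or behind the X-ray
    source under either pose invalidate the evaluation and raise.
    """
    corners = volume.world_corners() if points is None else np.atleast_2d(np.asarray(points, float))
    p_ref = project_points(corners, t_ref, geom)
    p_reg = project_points(corners, t_reg, geom)
    if np.isnan(p_ref).any() or np.isnan(p_reg).any():
        raise ValueError("a bounding-box corner projected from behind the source; MPE undefined")
    dist = np.linalg.norm(p_ref - p_reg, axis=1).mean()
    if unit == "mm":
        return float(dist * geom.pixel_spacing)
    if unit != "px":
        raise ValueError("unit must be 'px' or 'mm'")
    return float(dist)


def success_rate(mpes, threshold: float) -> float:
    """Fraction of registrations with MPE strictly below the threshold."""
    mpes = np.asarray(list(mpes), dtype=float)
    if mpes.size == 0:
        raise ValueError("success_rate of an empty list is undefined")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return float((mpes < threshold).mean())


def capture_range_histogram(records, n_bins: int = 10) -> list[CaptureRangeBin]:
    """Equal-count binning by initial MPE with per-bin median of final MPE.

    Records are sorted by ``mpe_before`` and split into ``n_bins`` bins of
    equal count; when the count does not divide evenly, earlier bins take
    one extra record (deterministic, order-stable).
    """
    records = list(records)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(records) < n_bins:
        raise ValueError(f"need at least {n_bins} records for {n_bins} bins, got {len(records)}")
    records.sort(key=lambda r: r.mpe_before)
    base, extra = divmod(len(records), n_bins)
    bins = []
    start = 0
    for i in range(n_bins):
        size = base + (1 if i < extra else 0)
        chunk = records[start : start + size]
        start += size
        bins.append(
            CaptureRangeBin(
                lo=chunk[0].mpe_before,
                hi=chunk[-1].mpe_before,
                median_after=float(np.median([r.mpe_after for r in chunk])),
                count=size,
            )
        )
    return bins


def divergence_point(histogram: list[CaptureRangeBin], success_level: float) -> float:
    """Initial-MPE level past which registration stops succeeding.

    The left edge of the first bin whose median final MPE exceeds
    ``success_level`` with every later bin also exceeding it; +inf when the
    medians never diverge.  A transient spike followed by recovery is not a
    divergence.
    """
    exceeded = [b.median_after > success_level for b in histogram]
    for i, exc in enumerate(exceeded):
        if exc and all(exceeded[i:]):
            return float(histogram[i].lo)
    return float("inf")


# -- reader study -------------------------------------------------------------

def _exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p-value.

    Zeros are dropped; ties get average ranks (doubled to keep the DP over
    integer sums exact).  The null enumerates all 2^n sign assignments via
    subset-sum dynamic programming, exact for any n that fits memory.
    """
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        return 1.0
    from scipy.stats import rankdata

    ranks2 = np.round(2 * rankdata(np.abs(diffs))).astype(int)
    w2 = int(ranks2[diffs > 0].sum())
    total = int(ranks2.sum())
    # dp[s] = number of sign assignments with positive-rank sum s
    dp = np.zeros(total + 1, dtype=float)
    dp[0] = 1.0
    for r in ranks2:  # doubled ranks are always >= 2
        dp[r:] += dp[:-r]
    dp /= dp.sum()
    mu = total / 2.0
    dev = abs(w2 - mu)
    sums = np.arange(total + 1)
    return float(dp[np.abs(sums - mu) >= dev - 1e-9].sum())


def signed_rank_test(scores, center: float = 3.0) -> float:
    """Exact two-sided signed-rank test of preference scores against 'tie'.

    Scores are centered (score - 3); the exact null distribution is used up
    to n = 25 non-zero differences, a normal approximation beyond.
    """
    diffs = np.asarray(list(scores), dtype=float) - center
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 1.0
    if nonzero.size <= 25:
        return _exact_signed_rank_p(diffs)
    from scipy.stats import wilcoxon

    return float(wilcoxon(nonzero, alternative="two-sided", correction=True).pvalue)


@dataclass
class PreferenceTally:
    preferred: dict
    ties: int
    n_comparisons: int
    p_values: dict


def tally_preferences(records) -> PreferenceTally:
    """Count how often each method was preferred, plus pairwise tests.

    Scores 1-2 count as a preference for the left method, 4-5 for the
    right, 3 as a tie.  For every ordered method pair present, a two-sided
    exact signed-rank test on the centered scores asks whether the reader
    systematically favored one side.
    """
    records = list(records)
    preferred: Counter = Counter()
    methods = set()
    ties = 0
    by_pair: dict = {}
    for r in records:
        if not isinstance(r, PreferenceRecord):
            raise TypeError("records must be PreferenceRecord instances")
        methods.update((r.left_method, r.right_method))
        if r.score <= 2:
            preferred[r.left_method] += 1
        elif r.score >= 4:
            preferred[r.right_method] += 1
        else:
            ties += 1
        by_pair.setdefault((r.left_method, r.right_method), []).append(r.score)
    p_values = {pair: signed_rank_test(scores) for pair, scores in by_pair.items()}
    out = {m: preferred.get(m, 0) for m in sorted(methods)}
    return PreferenceTally(preferred=out, ties=ties, n_comparisons=len(records), p_values=p_values)
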