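"""Behavioral analysis of dyadic anti-phase tapping.

Quantities implemented:

* inter-tap interval (ITI): first differences of tap onsets, by default on
  the merged, time-sorted dyadic stream (both participants' taps
  interleaved), with per-participant ITI also available;
* relative phase (RP): the position of participant 2's tap within
  participant 1's concurrent inter-tap interval, scaled to [0, 360)
  degrees — 180 deg is perfect anti-phase;
* SDRP: the circular standard deviation sqrt(-2 ln R) of the RP
  distribution, where R is the resultant length of the mean RP unit
  vector — the instability of anti-phase coordination;
* Welch's unequal-variance t-test for group comparisons of these summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats


class InvalidTapRecordError(ValueError):
    pass


@dataclass
class TapRecord:
    """Ordered tap-onset times (seconds) for one participant in one session."""

    onsets: np.ndarray
    participant_id: str = ""
    condition: str | None = None

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        if onsets.ndim != 1 or onsets.size < 2:
            raise InvalidTapRecordError("need at least 2 tap onsets")
        if not np.all(np.diff(onsets) > 0):
            raise InvalidTapRecordError("tap onsets must be strictly increasing")
        self.onsets = onsets


@dataclass
class RelativePhaseSeries:
    """Relative phase samples in degrees [0, 360), with matching diagnostics.

    ``n_skipped`` counts participant-1 intervals that contained no
    participant-2 tap; ``n_multiple`` counts intervals with more than one
    (only the first is used).
    """

    rp_values: np.ndarray
    n_skipped: int = 0
    n_multiple: int = 0

    def __post_init__(self) -> None:
        rp = np.asarray(self.rp_values, dtype=float)
        self.rp_values = np.mod(rp, 360.0)

    @property
    def n_points(self) -> int:
        return self.rp_values.size


@dataclass
class BehavioralSummary:
    """Per-session behavioral scalars for one dyad."""

    mean_iti: float
    sdrp: float
    resultant_length: float
    n_matched: int = 0
    n_skipped: int = 0
    degenerate: bool = False  # R == 0: SDRP reported as +inf


def compute_iti(taps: TapRecord) -> tuple[np.ndarray, float]:
    """Inter-tap intervals ``t(m+1) - t(m)`` and their mean, seconds."""
    iti = np.diff(taps.onsets)
    return iti, float(iti.mean())


def merge_tap_streams(p1: TapRecord, p2: TapRecord) -> TapRecord:
    """Time-sorted merge of both participants' onsets into one dyadic stream.

    The dyadic mean ITI is defined on this merged stream (at perfect
    anti-phase it is half each participant's own ITI).
    """
    merged = np.sort(np.concatenate([p1.onsets, p2.onsets]))
    if not np.all(np.diff(merged) > 0):
        merged = np.unique(merged)
    cond = p1.condition if p1.condition == p2.condition else None
    return TapRecord(onsets=merged, participant_id=f"{p1.participant_id}+{p2.participant_id}",
                     condition=cond)


def relative_phase(p1: TapRecord, p2: TapRecord) -> RelativePhaseSeries:
    """Relative phase of p2's taps within p1's intervals, degrees [0, 360).

    For each participant-1 interval ``[t(n), t(n+1))`` the matched
    participant-2 tap is the first p2 onset strictly inside it;
    ``RP_n = (t(n)_p2 - t(n)_p1) / (t(n+1)_p1 - t(n)_p1) * 360``. Intervals
    with no p2 tap are skipped and counted; with several, only the first is
    used and the excess counted.
    """
    t1 = p1.onsets
    t2 = p2.onsets
    rp = []
    n_skipped = 0
    n_multiple = 0
    for n in range(t1.size - 1):
        lo, hi = t1[n], t1[n + 1]
        inside = t2[(t2 >= lo) & (t2 < hi)]  # a coincident tap counts as RP = 0
        if inside.size == 0:
            n_skipped += 1
            continue
        if inside.size > 1:
            n_multiple += 1
        rp.append((inside[0] - lo) / (hi - lo) * 360.0)
    return RelativePhaseSeries(
        rp_values=np.asarray(rp), n_skipped=n_skipped, n_multiple=n_multiple
    )


def circular_sdrp(rp: RelativePhaseSeries) -> tuple[float, float]:
    """Circular SD and resultant length (SDRP, R) of a relative-phase series.

    ``R = |mean exp(j * RP)|`` with RP in radians; ``SDRP = sqrt(-2 ln R)``.
    At R = 0 (e.g. antipodal phases) SDRP is reported as ``inf``.
    """
    if rp.n_points < 1:
        raise InvalidTapRecordError("need at least one relative-phase sample")
    radians = np.deg2rad(rp.rp_values)
    resultant = np.exp(1j * radians).mean()
    r = float(np.abs(resultant))
    r = min(r, 1.0)
    if r <= 0.0 or math.isclose(r, 0.0, abs_tol=1e-15):
        return math.inf, 0.0
    sdrp = math.sqrt(-2.0 * math.log(r)) if r < 1.0 else 0.0
    return sdrp, r


def summarize_behavior(p1: TapRecord, p2: TapRecord) -> BehavioralSummary:
    """Full behavioral summary of one dyadic session."""
    merged = merge_tap_streams(p1, p2)
    _, mean_iti = compute_iti(merged)
    rp = relative_phase(p1, p2)
    sdrp, r = circular_sdrp(rp)
    return BehavioralSummary(
        mean_iti=mean_iti,
        sdrp=sdrp,
        resultant_length=r,
        n_matched=rp.n_points,
        n_skipped=rp.n_skipped,
        degenerate=math.isinf(sdrp),
    )


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, Welch df, two-sided p).

    Zero variance in both groups with equal means returns (0, df, 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must contain only finite values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, float(a.size + b.size - 2), 0.0
    res = sstats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
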