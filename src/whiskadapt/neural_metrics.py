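"""Touch-aligned spike metrics: counting, responsiveness, PSTH, latency, ROC.

Responses are spike counts in 30 ms windows starting at touch onset
(half-open ``[onset, onset + 30)``); pre-touch activity is the matching
30 ms window before onset.  Touch discriminability is quantified as the
area under the ROC curve between touch-evoked counts and "noise" counts
sampled from touch-free periods: before the first touch of a trial for
first touches, and from inter-touch gaps for later touches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SPIKE_COLUMNS",
    "SpikeTrain",
    "AlignedResponse",
    "ResponsivenessResult",
    "count_spikes",
    "window_counts",
    "aligned_counts",
    "is_touch_responsive",
    "psth",
    "latency_from_rates",
    "response_latency",
    "roc_auc",
    "noise_window_starts",
    "population_response",
    "per_order_mean_counts",
    "normalized_attenuation",
]

#: Schema of ``spikes.csv``.
SPIKE_COLUMNS = ["session_id", "unit_id", "spike_time_ms"]


@dataclass(frozen=True)
class SpikeTrain:
    """One unit's spike times (ms, sorted ascending) within a session."""

    unit_id: str
    session_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1D array")
        if len(t) and (not np.all(np.isfinite(t)) or np.any(t < 0)):
            raise ValueError("spike times must be finite and non-negative")
        if np.any(np.diff(t) < 0):
            raise ValueError("spike times must be sorted ascending")
        t.setflags(write=False)
        object.__setattr__(self, "times", t)

    @classmethod
    def from_table(cls, spikes: pd.DataFrame) -> list["SpikeTrain"]:
        """Build one train per unit from a spikes table (sorted on load)."""
        trains = []
        for (session, unit), g in sorted(
            spikes.groupby(["session_id", "unit_id"]), key=lambda kv: kv[0]
        ):
            trains.append(
                cls(
                    unit_id=str(unit),
                    session_id=str(session),
                    times=np.sort(g["spike_time_ms"].to_numpy(dtype=float)),
                )
            )
        return trains


def _times(train) -> np.ndarray:
    return train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)


def count_spikes(train, start: float, end: float) -> int:
    """Number of spikes in the half-open window ``[start, end)``."""
    if not start < end:
        raise ValueError(f"window start {start} must precede end {end}")
    t = _times(train)
    i, j = np.searchsorted(t, [start, end], side="left")
    return int(j - i)


def window_counts(train, starts, window_ms: float = 30.0) -> np.ndarray:
    """Spike counts in ``[s, s + window_ms)`` for each start ``s``."""
    t = _times(train)
    starts = np.asarray(starts, dtype=float)
    lo = np.searchsorted(t, starts, side="left")
    hi = np.searchsorted(t, starts + window_ms, side="left")
    return (hi - lo).astype(int)


@dataclass
class AlignedResponse:
    """Per-touch post-onset and pre-onset spike counts for one unit."""

    post: np.ndarray  # counts in [onset, onset + window)
    pre: np.ndarray   # counts in [onset - window, onset)


def aligned_counts(train, onsets, window_ms: float = 30.0) -> AlignedResponse:
    onsets = np.asarray(onsets, dtype=float)
    return AlignedResponse(
        post=window_counts(train, onsets, window_ms),
        pre=window_counts(train, onsets - window_ms, window_ms),
    )


@dataclass
class ResponsivenessResult:
    """Outcome of the touch-responsiveness screen for one unit.

    ``responsive`` is ``None`` (undetermined) when fewer than the minimum
    number of touches is available.
    """

    responsive: bool | None
    effect: float   # mean(post) - mean(pre), spikes per window
    p_value: float
    n_touches: int


def is_touch_responsive(
    train,
    onsets,
    window_ms: float = 30.0,
    alpha: float = 0.05,
    min_touches: int = 10,
) -> ResponsivenessResult:
    """Screen a unit for an increase in firing rate shortly after touch.

    Paired one-sided Wilcoxon signed-rank test on (post - pre) spike counts
    across touches; counts are non-Gaussian, so a rank test is used.  A unit
    is responsive when the post-touch mean exceeds the pre-touch mean at the
    given significance level.
    """
    ar = aligned_counts(train, onsets, window_ms)
    n = len(ar.post)
    effect = float(ar.post.mean() - ar.pre.mean()) if n else float("nan")
    if n < min_touches:
        return ResponsivenessResult(None, effect, float("nan"), n)
    diffs = ar.post.astype(float) - ar.pre.astype(float)
    if np.all(diffs == 0):
        p = 1.0
    else:
        p = float(
            stats.wilcoxon(
                ar.post, ar.pre, alternative="greater", zero_method="wilcox"
            ).pvalue
        )
    return ResponsivenessResult(bool(p < alpha and effect > 0), effect, p, n)


def psth(
    train,
    events,
    bin_ms: float = 1.0,
    window: tuple[float, float] = (-30.0, 60.0),
    smooth_ms: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-aligned mean firing rate (spikes/s) in fixed bins.

    Returns ``(edges, rates)`` where ``edges`` has one more element than
    ``rates`` and bin ``i`` covers ``[edges[i], edges[i+1])`` relative to
    event time.  Optional boxcar smoothing (label-preserving, for display).
    """
    if bin_ms < 1.0:
        raise ValueError("bin must be >= 1 ms")
    events = np.asarray(events, dtype=float)
    if len(events) == 0:
        raise ValueError("empty event list")
    t = _times(train)
    lo, hi = float(window[0]), float(window[1])
    edges = np.arange(lo, hi + bin_ms / 2, bin_ms)
    offsets = []
    for e in events:
        i, j = np.searchsorted(t, [e + lo, e + hi], side="left")
        offsets.append(t[i:j] - e)
    offsets = np.concatenate(offsets) if offsets else np.array([])
    counts, _ = np.histogram(offsets, bins=edges)
    rates = counts / (len(events) * bin_ms / 1000.0)
    if smooth_ms is not None:
        k = max(1, int(round(smooth_ms / bin_ms)))
        rates = np.convolve(rates, np.ones(k) / k, mode="same")
    return edges, rates


def latency_from_rates(
    rates: np.ndarray,
    n_baseline_bins: int,
    bin_ms: float = 1.0,
    max_latency_ms: float = 30.0,
    n_sd: float = 2.0,
) -> tuple[float, float]:
    """First post-event time at which a PSTH exceeds baseline mean + n_sd*SD.

    ``rates`` is a 1 ms-resolution PSTH whose first ``n_baseline_bins`` bins
    are pre-event baseline.  Returns ``(latency_ms, threshold)``; latency is
    NaN when the threshold is never exceeded within ``max_latency_ms``.
    """
    rates = np.asarray(rates, dtype=float)
    base = rates[:n_baseline_bins]
    threshold = float(base.mean() + n_sd * base.std())
    n_post = int(round(max_latency_ms / bin_ms))
    post = rates[n_baseline_bins : n_baseline_bins + n_post]
    above = np.flatnonzero(post > threshold)
    latency = float(above[0] * bin_ms) if len(above) else float("nan")
    return latency, threshold

def response_latency(
    train,
    onsets,
    window_ms: float = 30.0,
    baseline_ms: float = 30.0,
) -> float:
    """Response latency (ms) of a unit to a set of touch onsets.

    Computed on the 1 ms touch-aligned PSTH as the first time after onset at
    which the rate exceeds the pre-touch baseline mean + 2 SD
    (baseline = the ``baseline_ms`` before onset); NaN if never exceeded
    within ``window_ms``.  This threshold rule is the least-constrained
    convention in the package (see the methods note).
    """
    _, rates = psth(train, onsets, bin_ms=1.0, window=(-baseline_ms, window_ms))
    latency, _ = latency_from_rates(
        rates, int(round(baseline_ms)), 1.0, window_ms
    )
    return latency


def latency_by_order(
    train, touches: pd.DataFrame, max_order: int = 5, window_ms: float = 30.0
) -> dict:
    """Per-touch-order response latency; orders above ``max_order`` pooled."""
    out = {}
    for k in range(1, max_order + 1):
        onsets = touches.loc[touches["order"] == k, "onset_ms"]
        if len(onsets):
            out[k] = response_latency(train, onsets, window_ms)
    pooled = touches.loc[touches["order"] > max_order, "onset_ms"]
    if len(pooled):
        out[f">{max_order}"] = response_latency(train, pooled, window_ms)
    return out


def roc_auc(signal_counts, noise_counts) -> float:
    """Area under the ROC curve for discriminating signal from noise counts.

    Computed as the normalised Mann-Whitney rank statistic
    ``P(s > n) + 0.5 P(s = n)``, equal to the area traced by sweeping an
    integer count threshold.  0.5 is chance level.
    """
    s = np.asarray(signal_counts, dtype=float)
    n = np.asarray(noise_counts, dtype=float)
    if len(s) == 0 or len(n) == 0:
        raise ValueError("signal and noise count lists must be non-empty")
    ranks = stats.rankdata(np.concatenate([s, n]))
    u = ranks[: len(s)].sum() - len(s) * (len(s) + 1) / 2.0
    return float(u / (len(s) * len(n)))


def noise_window_starts(
    trial_onset: float, onsets, window_ms: float = 30.0
) -> tuple[list[float], list[float]]:
    """Deterministic noise-window start times for ROC analysis.

    First-touch noise windows tile ``[trial_onset, first onset)``; later
    noise windows tile each inter-touch interval starting ``window_ms``
    after the previous onset, so no noise window overlaps any
    ``[onset, onset + window_ms)`` response window.  All available
    non-overlapping windows are used (no random sampling).
    """
    onsets = np.sort(np.asarray(onsets, dtype=float))
    first: list[float] = []
    if len(onsets):
        t = float(trial_onset)
        while t + window_ms <= onsets[0]:
            first.append(t)
            t += window_ms
    later: list[float] = []
    for k in range(len(onsets) - 1):
        t = onsets[k] + window_ms
        while t + window_ms <= onsets[k + 1]:
            later.append(float(t))
            t += window_ms
    return first, later


def population_response(
    trains: list, onsets, window_ms: float = 30.0
) -> np.ndarray:
    """Summed post-onset counts over simultaneously recorded units."""
    if not trains:
        raise ValueError("empty population")
    total = np.zeros(len(np.atleast_1d(onsets)), dtype=int)
    for train in trains:
        total += window_counts(train, onsets, window_ms)
    return total


def per_order_mean_counts(
    counts, orders, max_order: int = 8
) -> np.ndarray:
    """Mean spike count per touch order (NaN where an order is absent)."""
    counts = np.asarray(counts, dtype=float)
    orders = np.asarray(orders)
    out = np.full(max_order, np.nan)
    for k in range(1, max_order + 1):
        mask = orders == k
        if mask.any():
            out[k - 1] = counts[mask].mean()
    return out


def normalized_attenuation(counts, orders, max_order: int = 8) -> np.ndarray:
    """Per-order mean count divided by the first-touch mean count."""
    means = per_order_mean_counts(counts, orders, max_order)
    if not np.isfinite(means[0]) or means[0] == 0:
        warnings.warn("first-touch mean count unavailable or zero")
        return np.full(max_order, np.nan)
    return means / means[0]
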