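"""Seeded generator of synthetic pole-detection sessions with ground truth.

Emulates the statistical structure the analysis pipeline assumes, with
known injected parameters so every stage can be tested for recovery:

* Go/NoGo trials with hit/miss outcomes; NoGo trials carry no touches.
* Variable touches per trial (negative binomial; more touches on hits than
  misses), log-normal inter-touch intervals and touch durations.
* Touch strengths |delta kappa_3D| drawn log-normal with a geometric
  per-order decay (``motor_decay``) emulating motor adaptation.
* Unit spike counts linearly tuned to touch strength, with order-dependent
  intercept/slope multipliers (``sa_intercept_ratio``/``sa_slope_ratio``
  applied from the second touch on) emulating sensory adaptation; the
  adaptation state can track the pooled touch order or, when
  ``whisker_specific`` is set, the per-whisker order.
* Counts are Poisson-realised (``noise="poisson"``), with evoked spikes
  placed in the response window on top of homogeneous background spiking,
  or left as exact expectations (``noise="none"``) for limit-case tests.

Distribution families and parameter defaults are descriptive choices tuned
to the qualitative shape of behavioural touch statistics, not canonical
values.  Randomness uses one stream per trial derived from the session
seed by counter, so partial regeneration is stable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .touch_events import order_touches

__all__ = [
    "COUNT_COLUMNS",
    "SessionConfig",
    "GroundTruth",
    "Session",
    "generate_session",
    "generate_bezier_frames",
    "implied_alpha",
]

#: Schema of ``counts.csv`` (evoked spike counts per touch per unit).
COUNT_COLUMNS = ["touch_id", "unit_id", "count"]


class ConfigError(ValueError):
    """Invalid synthetic-session configuration."""


@dataclass
class SessionConfig:
    """Parameters of one synthetic session.  Seed is mandatory.

    Rates and counts are per 30 ms response window unless noted; strengths
    are |delta kappa_3D| in 1/mm; times in ms.
    """

    seed: int
    n_trials: int = 135
    p_go: float = 0.55
    hit_rate: float = 0.81
    p_false_alarm: float = 0.15
    # touches per Go trial: negative binomial, truncated to >= 1
    touches_hit_mean: float = 10.5
    touches_hit_sd: float = 5.7
    touches_miss_mean: float = 5.0
    touches_miss_sd: float = 7.7
    # inter-touch intervals and durations: log-normal
    iti_median_ms: float = 45.0
    iti_sigma: float = 0.55
    iti_min_ms: float = 10.0
    iti_max_ms: float = 200.0
    duration_median_ms: float = 30.0
    duration_sigma: float = 0.7
    # touch strength |delta kappa_3D|: log-normal, random sign
    strength_median: float = 0.02
    strength_sigma: float = 0.7
    p_positive: float = 0.5
    motor_decay: float = 0.85      # per-order multiplicative strength ratio
    # units: linear tuning count = slope * |dk| + intercept, per 30 ms
    n_units: int = 6
    slope_mean: float = 60.0
    slope_sd: float = 15.0
    intercept_mean: float = 1.5
    intercept_sd: float = 0.4
    sa_intercept_ratio: float = 0.32   # applied for touch order >= 2
    sa_slope_ratio: float = 0.8
    whisker_specific: bool = False     # adaptation tracks per-whisker order
    two_whiskers: bool = True
    noise: str = "poisson"             # "poisson" | "none"
    baseline_rate_hz: float = 1.0
    # trial timing
    trial_len_ms: int = 3000
    pole_up_ms: int = 500
    pole_down_ms: int = 1500
    response_window_ms: int = 30
    # whisker geometry for frame generation
    rest_curvature: float = 0.05       # 1/mm
    whisker_length_mm: float = 16.0

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        for name in ("p_go", "hit_rate", "p_false_alarm", "p_positive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in (
            "touches_hit_mean", "touches_miss_mean", "iti_median_ms",
            "duration_median_ms", "strength_median", "slope_mean",
            "intercept_mean",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("motor_decay", "sa_intercept_ratio", "sa_slope_ratio"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name}={v} outside (0, 1]")
        if self.baseline_rate_hz < 0:
            raise ConfigError("baseline_rate_hz must be >= 0")
        if self.noise not in ("poisson", "none"):
            raise ConfigError(f"unknown noise mode {self.noise!r}")
        if not (0 <= self.pole_up_ms < self.pole_down_ms <= self.trial_len_ms):
            raise ConfigError("pole window must fit inside the trial")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """The generator's injected schedules, stored alongside every session."""

    unit_slopes: np.ndarray
    unit_intercepts: np.ndarray
    sa_intercept_ratio: float
    sa_slope_ratio: float
    motor_decay: float
    whisker_specific: bool
    mean_abs_strength: float        # E|dk| for first touches
    baseline_count: float           # expected background count per window
    implied_alpha: float

    def expected_strength(self, order: int) -> float:
        return self.mean_abs_strength * self.motor_decay ** (order - 1)

    def tuning_for_order(self, order: int) -> tuple[np.ndarray, np.ndarray]:
        """True per-unit (slope, intercept) at a given adaptation order."""
        if order <= 1:
            return self.unit_slopes, self.unit_intercepts
        return (
            self.unit_slopes * self.sa_slope_ratio,
            self.unit_intercepts * self.sa_intercept_ratio,
        )

    def to_json(self) -> str:
        d = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self).items()
        }
        return json.dumps(d, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["unit_slopes"] = np.asarray(d["unit_slopes"], dtype=float)
        d["unit_intercepts"] = np.asarray(d["unit_intercepts"], dtype=float)
        return cls(**d)


@dataclass
class Session:
    """A generated (or loaded) session: tables plus optional ground truth."""

    session_id: str
    config: SessionConfig | None
    trials: pd.DataFrame
    touches: pd.DataFrame
    spikes: pd.DataFrame
    counts: pd.DataFrame
    ground_truth: GroundTruth | None = None

    def spike_trains(self) -> list:
        from .neural_metrics import SpikeTrain

        if len(self.spikes) == 0:
            return []
        return SpikeTrain.from_table(self.spikes)

    def count_matrix(self) -> pd.DataFrame:
        """Evoked counts as touches x units, rows aligned with ``touches``."""
        wide = self.counts.pivot(
            index="touch_id", columns="unit_id", values="count"
        )
        return wide.loc[self.touches["touch_id"].to_numpy()].reset_index(
            drop=True
        )


def _draw_n_touches(rng: np.random.Generator, mean: float, sd: float) -> int:
    var = sd**2
    for _ in range(100):
        if var <= mean:
            n = int(rng.poisson(mean))
        else:
            r = mean**2 / (var - mean)
            p = r / (r + mean)
            n = int(rng.negative_binomial(r, p))
        if n >= 1:
            return n
    return 1


def _unit_params(config: SessionConfig) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng([config.seed, 0])
    slopes = np.clip(
        rng.normal(config.slope_mean, config.slope_sd, config.n_units),
        5.0, None,
    )
    intercepts = np.clip(
        rng.normal(
            config.intercept_mean, config.intercept_sd, config.n_units
        ),
        0.2, None,
    )
    return slopes, intercepts


def generate_session(config: SessionConfig) -> Session:
    """Generate one synthetic session; deterministic given the seed."""
    config.validate()
    slopes, intercepts = _unit_params(config)
    unit_ids = [f"u{u:02d}" for u in range(config.n_units)]
    window = float(config.response_window_ms)
    mu_log_s = np.log(config.strength_median)
    mu_log_iti = np.log(config.iti_median_ms)
    mu_log_dur = np.log(config.duration_median_ms)

    trial_rows, touch_rows, count_rows = [], [], []
    spike_times: dict[str, list[np.ndarray]] = {u: [] for u in unit_ids}
    touch_id = 0
    session_id = f"synth-{config.seed}"

    for t in range(config.n_trials):
        rng = np.random.default_rng([config.seed, 1 + t])
        start = t * config.trial_len_ms
        pole_up = start + config.pole_up_ms
        pole_down = start + config.pole_down_ms
        is_go = rng.random() < config.p_go
        if not is_go:
            outcome = (
                "false_alarm"
                if rng.random() < config.p_false_alarm
                else "correct_rejection"
            )
            trial_rows.append((t, "nogo", outcome, pole_up, pole_down))
            if config.noise == "poisson":
                _background(rng, config, unit_ids, start, spike_times)
            continue
        outcome = "hit" if rng.random() < config.hit_rate else "miss"
        if outcome == "hit":
            n_target = _draw_n_touches(
                rng, config.touches_hit_mean, config.touches_hit_sd
            )
        else:
            n_target = _draw_n_touches(
                rng, config.touches_miss_mean, config.touches_miss_sd
            )
        # touch onsets: first after a whisk-in delay, then log-normal ITIs;
        # touches only occur while the pole is in reach
        onsets = [pole_up + rng.uniform(20.0, 150.0)]
        for _ in range(n_target - 1):
            iti = np.clip(
                rng.lognormal(mu_log_iti, config.iti_sigma),
                config.iti_min_ms, config.iti_max_ms,
            )
            onsets.append(onsets[-1] + iti)
        onsets = np.array([o for o in onsets if o < pole_down])
        n = len(onsets)
        if n == 0:
            trial_rows.append((t, "go", outcome, pole_up, pole_down))
            if config.noise == "poisson":
                _background(rng, config, unit_ids, start, spike_times)
            continue
        # touches last at least 6 ms so every strength window lies in contact
        durations = np.clip(
            rng.lognormal(mu_log_dur, config.duration_sigma, n), 6.0, None
        )
        # keep touches non-overlapping (also across whiskers)
        for i in range(n - 1):
            durations[i] = min(durations[i], onsets[i + 1] - onsets[i] - 1.0)
        durations[-1] = min(
            durations[-1], start + config.trial_len_ms - onsets[-1] - 1.0
        )
        if config.two_whiskers:
            whiskers = np.where(rng.random(n) < 0.5, "C1", "C2")
        else:
            whiskers = np.full(n, "C1")
        orders = np.arange(1, n + 1)
        per_whisker_order = np.empty(n, dtype=int)
        seen: dict[str, int] = {}
        for i, w in enumerate(whiskers):
            seen[w] = seen.get(w, 0) + 1
            per_whisker_order[i] = seen[w]
        mags = rng.lognormal(mu_log_s, config.strength_sigma, n)
        mags = mags * config.motor_decay ** (orders - 1)
        signs = np.where(rng.random(n) < config.p_positive, 1.0, -1.0)
        strengths = signs * mags

        k_eff = per_whisker_order if config.whisker_specific else orders
        for i in range(n):
            touch_rows.append(
                (
                    touch_id, t, whiskers[i], onsets[i],
                    onsets[i] + durations[i], int(orders[i]),
                    strengths[i], mags[i],
                )
            )
            adapted = k_eff[i] >= 2
            slope_k = slopes * (config.sa_slope_ratio if adapted else 1.0)
            int_k = intercepts * (
                config.sa_intercept_ratio if adapted else 1.0
            )
            mu = np.maximum(0.0, slope_k * mags[i] + int_k)
            if config.noise == "poisson":
                cnt = rng.poisson(mu).astype(float)
                for u, uid in enumerate(unit_ids):
                    if cnt[u] > 0:
                        evoked = onsets[i] + np.sort(
                            rng.uniform(5.0, window, int(cnt[u]))
                        )
                        spike_times[uid].append(evoked)
            else:
                cnt = mu
            for u, uid in enumerate(unit_ids):
                count_rows.append((touch_id, uid, cnt[u]))
            touch_id += 1
        trial_rows.append((t, "go", outcome, pole_up, pole_down))
        if config.noise == "poisson":
            _background(rng, config, unit_ids, start, spike_times)

    trials = pd.DataFrame(
        trial_rows,
        columns=["trial_id", "kind", "outcome", "pole_up_ms", "pole_down_ms"],
    )
    touches = pd.DataFrame(
        touch_rows,
        columns=[
            "touch_id", "trial_id", "whisker_id", "onset_ms", "offset_ms",
            "order", "strength", "abs_strength",
        ],
    )
    if len(touches):
        # re-derive orders through the pipeline's own ordering operation
        touches = order_touches(touches).drop(columns=["simultaneous_onset"])
        touches = touches.sort_values("touch_id").reset_index(drop=True)
    counts = pd.DataFrame(count_rows, columns=COUNT_COLUMNS)
    spike_rows = []
    for uid in unit_ids:
        if spike_times[uid]:
            times = np.sort(np.concatenate(spike_times[uid]))
            spike_rows.append(
                pd.DataFrame(
                    {
                        "session_id": session_id,
                        "unit_id": uid,
                        "spike_time_ms": times,
                    }
                )
            )
    spikes = (
        pd.concat(spike_rows, ignore_index=True)
        if spike_rows
        else pd.DataFrame(columns=["session_id", "unit_id", "spike_time_ms"])
    )
    gt = GroundTruth(
        unit_slopes=slopes,
        unit_intercepts=intercepts,
        sa_intercept_ratio=config.sa_intercept_ratio,
        sa_slope_ratio=config.sa_slope_ratio,
        motor_decay=config.motor_decay,
        whisker_specific=config.whisker_specific,
        mean_abs_strength=float(
            config.strength_median * np.exp(config.strength_sigma**2 / 2)
        ),
        baseline_count=float(
            config.n_units * config.baseline_rate_hz * window / 1000.0
        ),
        implied_alpha=implied_alpha(config, slopes, intercepts),
    )
    return Session(
        session_id=session_id,
        config=config,
        trials=trials,
        touches=touches,
        spikes=spikes,
        counts=counts,
        ground_truth=gt,
    )


def _background(rng, config, unit_ids, start, spike_times) -> None:
    lam = config.baseline_rate_hz * config.trial_len_ms / 1000.0
    if lam <= 0:
        return
    for uid in unit_ids:
        n_b = int(rng.poisson(lam))
        if n_b:
            spike_times[uid].append(
                start + np.sort(rng.uniform(0.0, config.trial_len_ms, n_b))
            )


def _order_weights(config: SessionConfig, k_max: int = 60) -> np.ndarray:
    """P(a Go trial reaches touch order k), k = 1..k_max, hit/miss mixed."""

    def sf(k, mean, sd):
        var = sd**2
        if var <= mean:
            return stats.poisson.sf(k - 1, mean)
        r = mean**2 / (var - mean)
        p = r / (r + mean)
        return stats.nbinom.sf(k - 1, r, p)

    ks = np.arange(1, k_max + 1)
    w = config.hit_rate * sf(
        ks, config.touches_hit_mean, config.touches_hit_sd
    ) + (1 - config.hit_rate) * sf(
        ks, config.touches_miss_mean, config.touches_miss_sd
    )
    return w


def implied_alpha(
    config: SessionConfig,
    slopes: np.ndarray | None = None,
    intercepts: np.ndarray | None = None,
) -> float:
    """Closed-form alpha under the generator's noiseless expectations.

    Uses expected (mean) population rates; the pipeline estimate uses
    medians, so agreement is approximate away from the exact limit cases
    (motor-only decay gives 0, sensitivity-only decay gives 1, both exact).
    NaN when the model implies no attenuation.
    """
    S = float(
        np.sum(slopes)
        if slopes is not None
        else config.n_units * config.slope_mean
    )
    I = float(
        np.sum(intercepts)
        if intercepts is not None
        else config.n_units * config.intercept_mean
    )
    b = config.n_units * config.baseline_rate_hz * config.response_window_ms / 1000.0
    sbar = config.strength_median * np.exp(config.strength_sigma**2 / 2)
    r_i, r_s, m = (
        config.sa_intercept_ratio,
        config.sa_slope_ratio,
        config.motor_decay,
    )
    w = _order_weights(config)
    w_later = w[1:] / w[1:].sum()
    ks = np.arange(2, len(w) + 1)
    fr1 = S * sbar + I + b
    fr1_pred = r_s * S * sbar + r_i * I + b
    fr_later = float(
        np.sum(w_later * (r_s * S * sbar * m ** (ks - 1) + r_i * I)) + b
    )
    if abs(fr1 - fr_later) < 1e-12:
        warnings.warn("model implies no attenuation; alpha undefined")
        return float("nan")
    return float((fr1 - fr1_pred) / (fr1 - fr_later))


def generate_bezier_frames(
    session: Session, whisk_freq_hz: float = 12.0, whisk_amp_mm: float = 1.0
) -> pd.DataFrame:
    """Per-frame Bezier control points reproducing the session's touches.

    For every 1 ms frame, control points are constructed so that the
    closed-form curvature at s = 0 equals the resting curvature plus, during
    a touch, that touch's signed strength (exact to numerical precision).
    Contact-free frames carry the resting curvature while the whisker base
    translates smoothly (whisking sinusoid), which leaves curvature
    unchanged.  A signed strength that would drive curvature below zero is
    unreachable and raises ``ValueError``.
    """
    cfg = session.config
    if cfg is None:
        raise ValueError("session has no config; cannot synthesise frames")
    d = cfg.whisker_length_mm / 2.0
    whiskers = ("C1", "C2") if cfg.two_whiskers else ("C1",)
    parts = []
    for row in session.trials.itertuples(index=False):
        start = int(row.pole_up_ms) - cfg.pole_up_ms
        times = start + np.arange(cfg.trial_len_ms)
        tt = session.touches[session.touches["trial_id"] == row.trial_id]
        for w_i, wid in enumerate(whiskers):
            kappa = np.full(cfg.trial_len_ms, cfg.rest_curvature)
            for touch in tt[tt["whisker_id"] == wid].itertuples(index=False):
                lo = int(np.floor(touch.onset_ms)) - start
                hi = int(np.ceil(touch.offset_ms)) - start
                kappa[max(lo, 0) : min(hi + 1, cfg.trial_len_ms)] = (
                    cfg.rest_curvature + touch.strength
                )
            if np.any(kappa < 0):
                bad = tt[tt["whisker_id"] == wid]["strength"].min()
                raise ValueError(
                    f"unreachable curvature target: rest "
                    f"{cfg.rest_curvature} + strength {bad} < 0 "
                    f"(trial {row.trial_id}, whisker {wid})"
                )
            phase = w_i * np.pi / 3.0
            base_x = whisk_amp_mm * np.sin(
                2.0 * np.pi * whisk_freq_hz * (times - start) / 1000.0 + phase
            )
            base_y = 2.0 * w_i
            h = 2.0 * kappa * d**2
            frame = pd.DataFrame(
                {
                    "time_ms": times,
                    "trial_id": row.trial_id,
                    "whisker_id": wid,
                    "p0x": base_x,
                    "p0y": base_y,
                    "p0z": 0.0,
                    "p1x": base_x + d,
                    "p1y": base_y,
                    "p1z": 0.0,
                    "p2x": base_x + 2.0 * d,
                    "p2y": base_y + h,
                    "p2z": 0.0,
                }
            )
            parts.append(frame)
    return pd.concat(parts, ignore_index=True)
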