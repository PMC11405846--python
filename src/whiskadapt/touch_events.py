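"""Touch-sequence structure within behavioural trials.

Touches are whisker-pole contact events inside Go trials of a pole-detection
task.  Their ordinal position ("touch order") within a trial is assigned by
onset time pooled across whiskers.  This module orders touches, summarises
their variability (counts, inter-touch intervals, durations, strengths,
split by hit vs miss outcome), and selects the adapting/test configurations
used by the whisker-specific adaptation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TOUCH_COLUMNS",
    "TRIAL_COLUMNS",
    "WsaSelection",
    "TouchStatistics",
    "order_touches",
    "touch_statistics",
    "select_wsa_trials",
]

#: Schema of ``touches.csv``.
TOUCH_COLUMNS = [
    "trial_id", "whisker_id", "onset_ms", "offset_ms",
    "order", "strength", "abs_strength",
]

#: Schema of ``trials.csv``.
TRIAL_COLUMNS = ["trial_id", "kind", "outcome", "pole_up_ms", "pole_down_ms"]


@dataclass(frozen=True)
class WsaSelection:
    """One trial eligible for the whisker-specific adaptation analysis.

    The first two touches of the trial ("adapting") were made by
    ``adapting_whisker``; ``test_orders`` are the pooled touch orders
    (all >= 3) of the test touches made by ``test_whisker`` that do not
    overlap in time with any touch of another whisker.
    """

    trial_id: int
    adapting_whisker: str
    test_whisker: str
    test_orders: tuple[int, ...]


def order_touches(touches: pd.DataFrame) -> pd.DataFrame:
    """Assign within-trial touch order 1..n by ascending onset.

    Order is assigned irrespective of whisker identity.  Simultaneous onsets
    across whiskers are tie-broken by ascending whisker label and flagged in
    the ``simultaneous_onset`` column.  Overlapping touches of the *same*
    whisker indicate a tracking inconsistency and raise ``ValueError``.
    """
    if len(touches) == 0:
        out = touches.copy()
        out["order"] = pd.Series(dtype=int)
        out["simultaneous_onset"] = pd.Series(dtype=bool)
        return out
    parts = []
    for trial, g in touches.groupby("trial_id", sort=True):
        g = g.sort_values(
            ["onset_ms", "whisker_id"], kind="stable"
        ).reset_index(drop=True)
        for wid, gw in g.groupby("whisker_id"):
            on = gw["onset_ms"].to_numpy()
            off = gw["offset_ms"].to_numpy()
            if np.any(on[1:] <= off[:-1]):
                raise ValueError(
                    f"overlapping touches for whisker {wid!r} in trial {trial}"
                )
        g["order"] = np.arange(1, len(g) + 1)
        g["simultaneous_onset"] = g["onset_ms"].duplicated(keep=False)
        parts.append(g)
    return pd.concat(parts, ignore_index=True)


@dataclass
class TouchStatistics:
    """Summary of touch variability in a session (Go trials)."""

    touches_per_trial: pd.Series          # indexed by trial_id, Go trials
    inter_touch_intervals_ms: np.ndarray  # consecutive onset differences
    touch_durations_ms: np.ndarray
    strengths: np.ndarray                 # signed delta kappa, 1/mm
    abs_strengths: np.ndarray
    by_outcome: pd.DataFrame              # hit/miss means

    def summary(self) -> pd.DataFrame:
        rows = {
            "touches_per_trial": self.touches_per_trial.to_numpy(dtype=float),
            "inter_touch_interval_ms": self.inter_touch_intervals_ms,
            "touch_duration_ms": self.touch_durations_ms,
            "abs_strength": self.abs_strengths,
        }
        return pd.DataFrame(
            {
                name: {
                    "mean": float(np.mean(v)) if len(v) else np.nan,
                    "sd": float(np.std(v)) if len(v) else np.nan,
                    "n": len(v),
                }
                for name, v in rows.items()
            }
        ).T


def touch_statistics(
    trials: pd.DataFrame, touches: pd.DataFrame
) -> TouchStatistics:
    """Touch-sequence statistics over Go trials, stratified hit vs miss.

    Inter-touch intervals are differences between consecutive touch onsets
    within a trial (pooled across whiskers).  Empty groups yield empty
    arrays / NaN means.
    """
    go = trials[trials["kind"] == "go"]
    if len(go) == 0:
        raise ValueError("touch_statistics requires at least one Go trial")
    counts = (
        touches.groupby("trial_id").size().reindex(go["trial_id"], fill_value=0)
    )
    itis, durations = [], []
    for _, g in touches.groupby("trial_id"):
        on = np.sort(g["onset_ms"].to_numpy(dtype=float))
        itis.append(np.diff(on))
        durations.append(
            g["offset_ms"].to_numpy(dtype=float)
            - g["onset_ms"].to_numpy(dtype=float)
        )
    itis = np.concatenate(itis) if itis else np.array([])
    durations = np.concatenate(durations) if durations else np.array([])
    strengths = touches["strength"].to_numpy(dtype=float)
    outcome = go.set_index("trial_id")["outcome"]
    rows = {}
    for oc in ("hit", "miss"):
        ids = outcome.index[outcome == oc]
        sub = touches[touches["trial_id"].isin(ids)]
        per_trial = counts.loc[ids] if len(ids) else pd.Series(dtype=float)
        sub_iti = []
        for _, g in sub.groupby("trial_id"):
            sub_iti.append(np.diff(np.sort(g["onset_ms"].to_numpy(float))))
        sub_iti = np.concatenate(sub_iti) if sub_iti else np.array([])
        rows[oc] = {
            "n_trials": len(ids),
            "mean_touches_per_trial": (
                float(per_trial.mean()) if len(per_trial) else np.nan
            ),
            "mean_inter_touch_interval_ms": (
                float(sub_iti.mean()) if len(sub_iti) else np.nan
            ),
            "mean_duration_ms": (
                float((sub["offset_ms"] - sub["onset_ms"]).mean())
                if len(sub)
                else np.nan
            ),
            "mean_abs_strength": (
                float(sub["strength"].abs().mean()) if len(sub) else np.nan
            ),
        }
    return TouchStatistics(
        touches_per_trial=counts,
        inter_touch_intervals_ms=itis,
        touch_durations_ms=durations,
        strengths=strengths,
        abs_strengths=np.abs(strengths),
        by_outcome=pd.DataFrame(rows).T,
    )


def _overlaps(onset, offset, other: pd.DataFrame) -> bool:
    # closed-interval intersection
    return bool(
        ((other["onset_ms"] <= offset) & (other["offset_ms"] >= onset)).any()
    )


def select_wsa_trials(
    trials: pd.DataFrame, touches: pd.DataFrame
) -> list[WsaSelection]:
    """Select trials for the whisker-specific adaptation analysis.

    A trial qualifies when (1) its first two touches were made by the same
    whisker (the adapting whisker), (2) a 3rd-or-later touch was made by a
    different whisker (the test whisker), and (3) that test touch does not
    overlap in time with any touch of another whisker.  The first
    non-overlapping candidate per trial is taken as the test touch: it is
    the test whisker's first touch of the trial and therefore probes the
    unadapted state.  The result is independent of trial storage order.
    """
    selections: list[WsaSelection] = []
    go_ids = sorted(trials.loc[trials["kind"] == "go", "trial_id"])
    for trial in go_ids:
        g = touches[touches["trial_id"] == trial].sort_values("order")
        if len(g) < 3:
            continue
        whiskers = g["whisker_id"].tolist()
        if whiskers[0] != whiskers[1]:
            continue
        w_ad = whiskers[0]
        candidates = g[(g["order"] >= 3) & (g["whisker_id"] != w_ad)]
        if len(candidates) == 0:
            continue
        w_test = candidates.iloc[0]["whisker_id"]
        others = g[g["whisker_id"] != w_test]
        for row in candidates[candidates["whisker_id"] == w_test].itertuples():
            if not _overlaps(row.onset_ms, row.offset_ms, others):
                selections.append(
                    WsaSelection(
                        trial_id=trial,
                        adapting_whisker=w_ad,
                        test_whisker=w_test,
                        test_orders=(int(row.order),),
                    )
                )
                break
    return selections
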