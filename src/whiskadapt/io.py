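"""CSV/JSON session persistence with schema validation."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .neural_metrics import SPIKE_COLUMNS
from .synthetic import COUNT_COLUMNS, GroundTruth, Session, SessionConfig
from .touch_events import TOUCH_COLUMNS, TRIAL_COLUMNS
from .whisker_geometry import FRAME_COLUMNS

__all__ = ["SchemaError", "save_session", "load_session"]


class SchemaError(ValueError):
    """A table failed schema validation; names the file and columns."""


_SCHEMAS = {
    "trials.csv": TRIAL_COLUMNS,
    "touches.csv": ["touch_id"] + TOUCH_COLUMNS,
    "spikes.csv": SPIKE_COLUMNS,
    "counts.csv": COUNT_COLUMNS,
    "frames.csv": FRAME_COLUMNS,
}


def _read(path: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _SCHEMAS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    return df


def save_session(session: Session, out_dir) -> Path:
    """Write a session's tables (and ground truth, if any) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(out / "trials.csv", index=False)
    session.touches.to_csv(out / "touches.csv", index=False)
    session.spikes.to_csv(out / "spikes.csv", index=False)
    session.counts.to_csv(out / "counts.csv", index=False)
    meta = {"session_id": session.session_id}
    if session.config is not None:
        meta["config"] = session.config.to_dict()
    (out / "session.json").write_text(json.dumps(meta, sort_keys=True, indent=2))
    if session.ground_truth is not None:
        (out / "ground_truth.json").write_text(session.ground_truth.to_json())
    return out


def load_session(data_dir) -> Session:
    """Load a session directory written by :func:`save_session`.

    Validates schemas and basic invariants (touch offsets after onsets,
    no touches on NoGo trials); spike times are sorted on load.
    """
    d = Path(data_dir)
    trials = _read(d / "trials.csv", "trials.csv")
    touches = _read(d / "touches.csv", "touches.csv")
    spikes_path = d / "spikes.csv"
    spikes = (
        _read(spikes_path, "spikes.csv")
        if spikes_path.exists()
        else pd.DataFrame(columns=SPIKE_COLUMNS)
    )
    counts_path = d / "counts.csv"
    counts = (
        _read(counts_path, "counts.csv")
        if counts_path.exists()
        else pd.DataFrame(columns=COUNT_COLUMNS)
    )
    if len(touches):
        bad = touches["offset_ms"] <= touches["onset_ms"]
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"touches.csv: offset_ms <= onset_ms at row {row}"
            )
        nogo = set(trials.loc[trials["kind"] == "nogo", "trial_id"])
        on_nogo = touches["trial_id"].isin(nogo)
        if on_nogo.any():
            row = int(np.flatnonzero(on_nogo.to_numpy())[0])
            raise SchemaError(
                f"touches.csv: touch on NoGo trial at row {row}"
            )
    if len(spikes):
        spikes = spikes.sort_values(
            ["session_id", "unit_id", "spike_time_ms"]
        ).reset_index(drop=True)
    meta_path = d / "session.json"
    session_id, config = d.name, None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        session_id = meta.get("session_id", session_id)
        if "config" in meta:
            config = SessionConfig(**meta["config"])
    gt_path = d / "ground_truth.json"
    gt = GroundTruth.from_json(gt_path.read_text()) if gt_path.exists() else None
    return Session(
        session_id=session_id,
        config=config,
        trials=trials,
        touches=touches,
        spikes=spikes,
        counts=counts,
        ground_truth=gt,
    )
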