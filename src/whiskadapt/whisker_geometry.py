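"""Quadratic-Bezier whisker geometry and touch-strength extraction.

A tracked whisker in one video frame (1 kHz frame rate) is a quadratic 3D
Bezier curve

    b(s) = (1-s)^2 P0 + 2 s (1-s) P1 + s^2 P2,      0 <= s <= 1,

where ``P0`` is the control point closest to the whisker base.  The curve's
intrinsic shape is summarised by the unsigned space-curve curvature

    kappa_3D(s) = |b'(s) x b''(s)| / |b'(s)|^3,

the reciprocal of the osculating-circle radius.  Under quasi-static contact,
the change in curvature at the base relative to the whisker's resting shape,

    delta_kappa(s) = kappa_3D(s) - kappa_3D,0(s),

is proportional to the bending moment at the follicle and serves as the
mechanical strength of a whisker-object touch.  Per-touch strength is the
mean of ``delta_kappa`` at ``s = 0`` over the 5 ms following touch onset
(half-open window, exactly 5 frames at 1 kHz).

Sign convention: ``kappa_3D`` is unsigned (>= 0); ``delta_kappa`` is signed
as contact-minus-rest and is negative when contact straightens the whisker.
No osculating-plane signed-curvature convention is attempted.

Units: mm for space, ms for time, 1/mm for curvature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FRAME_COLUMNS",
    "BezierFrame",
    "WhiskerKinematics",
    "DegenerateCurveWarning",
    "bezier_point",
    "bezier_derivatives",
    "curvature_3d",
    "delta_kappa",
    "touch_strength",
    "base_kinematics",
    "curvature_at_base_table",
    "rest_curvature_table",
    "touch_strengths_from_frames",
]

#: Schema of ``frames.csv``: one row per whisker per 1 ms frame.
FRAME_COLUMNS = [
    "time_ms", "trial_id", "whisker_id",
    "p0x", "p0y", "p0z", "p1x", "p1y", "p1z", "p2x", "p2y", "p2z",
]

_TANGENT_TOL = 1e-12


class DegenerateCurveWarning(UserWarning):
    """Curvature requested where the Bezier tangent vanishes.

    Occurs only for pathological tracking output (coincident control
    points); the curvature is reported as 0 in that case.
    """


@dataclass(frozen=True)
class BezierFrame:
    """One whisker's tracked shape at one video frame.

    Parameters
    ----------
    time
        Millisecond timestamp, frame-aligned at 1 kHz.
    whisker_id
        Whisker label (e.g. ``"C1"``, ``"C2"``, ``"C3"``).
    control_points
        ``(3, 3)`` array of 3D points in mm; row 0 is the control point
        closest to the whisker base.
    """

    time: int
    whisker_id: str
    control_points: np.ndarray

    def __post_init__(self) -> None:
        cp = np.array(self.control_points, dtype=float)
        if cp.shape != (3, 3):
            raise ValueError(
                f"control_points must have shape (3, 3); got {cp.shape}"
            )
        if not np.all(np.isfinite(cp)):
            raise ValueError("control_points must be finite")
        cp.setflags(write=False)
        object.__setattr__(self, "control_points", cp)


@dataclass
class WhiskerKinematics:
    """Curvature and base-motion summary of a whisker around a touch.

    ``base_displacement`` (D_b) is the Euclidean distance travelled by the
    whisker base (control point 0) over the strength window, and
    ``base_speed`` is D_b divided by the window length (mm/ms).
    """

    kappa3d: float | None = None
    kappa3d_rest: float | None = None
    delta_kappa: float | None = None
    base_displacement: float | None = None
    base_speed: float | None = None


def _check_s(s: float) -> float:
    s = float(s)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"curve parameter s={s} outside [0, 1]")
    return s


def _control_points(control_points) -> np.ndarray:
    cp = np.asarray(control_points, dtype=float)
    if cp.shape != (3, 3):
        raise ValueError(f"expected 3 control points in 3D; got shape {cp.shape}")
    return cp


def bezier_point(control_points, s: float) -> np.ndarray:
    """Evaluate the quadratic Bezier curve at parameter ``s`` in [0, 1]."""
    p0, p1, p2 = _control_points(control_points)
    s = _check_s(s)
    return (1.0 - s) ** 2 * p0 + 2.0 * s * (1.0 - s) * p1 + s**2 * p2


def bezier_derivatives(control_points, s: float) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivative of the curve with respect to ``s``.

    The second derivative of a quadratic Bezier curve is constant:
    ``b'' = 2 (P0 - 2 P1 + P2)``.
    """
    p0, p1, p2 = _control_points(control_points)
    s = _check_s(s)
    d1 = 2.0 * (1.0 - s) * (p1 - p0) + 2.0 * s * (p2 - p1)
    d2 = 2.0 * (p0 - 2.0 * p1 + p2)
    return d1, d2


def curvature_3d(control_points, s: float = 0.0) -> float:
    """Closed-form 3D curvature ``|b' x b''| / |b'|^3`` at parameter ``s``.

    Non-negative; equals the reciprocal of the osculating-circle radius.
    A degenerate tangent (``|b'(s)| = 0``) yields 0 with a
    :class:`DegenerateCurveWarning`.
    """
    d1, d2 = bezier_derivatives(control_points, s)
    n1 = float(np.linalg.norm(d1))
    if n1 < _TANGENT_TOL:
        warnings.warn(
            f"degenerate Bezier tangent at s={s}; reporting curvature 0",
            DegenerateCurveWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.linalg.norm(np.cross(d1, d2)) / n1**3)


def delta_kappa(
    contact_frame: BezierFrame, rest_curvature: float, s: float = 0.0
) -> float:
    """Signed curvature change of a contact frame relative to rest.

    ``rest_curvature`` must be estimated from contact-free frames of the
    same whisker (see :func:`rest_curvature_table`).
    """
    if rest_curvature is None or not np.isfinite(rest_curvature):
        raise ValueError(
            "no rest-curvature estimate for whisker "
            f"{contact_frame.whisker_id!r}"
        )
    return curvature_3d(contact_frame.control_points, s) - float(rest_curvature)


def touch_strength(
    frames: Iterable[BezierFrame],
    onset: int,
    rest_curvature: float,
    window_ms: int = 5,
) -> float:
    """Mean signed ``delta_kappa`` at s=0 over ``[onset, onset + window_ms)``.

    ``frames`` must cover every 1 ms timestamp in the half-open window
    (exactly ``window_ms`` frames at 1 kHz); missing timestamps raise a
    :class:`ValueError` listing them.
    """
    by_time = {int(f.time): f for f in frames}
    needed = range(int(onset), int(onset) + int(window_ms))
    missing = [t for t in needed if t not in by_time]
    if missing:
        raise ValueError(f"frames missing for times {missing} (ms)")
    values = [delta_kappa(by_time[t], rest_curvature) for t in needed]
    return float(np.mean(values))


def base_kinematics(
    frame_t0: BezierFrame, frame_t5: BezierFrame
) -> WhiskerKinematics:
    """Whisker-base displacement D_b and speed between two frames.

    The frames must belong to the same whisker; conventionally they are 5 ms
    apart (touch onset and onset + 5 ms).
    """
    if frame_t0.whisker_id != frame_t5.whisker_id:
        raise ValueError(
            f"whisker mismatch: {frame_t0.whisker_id!r} vs {frame_t5.whisker_id!r}"
        )
    dt = float(frame_t5.time - frame_t0.time)
    if dt <= 0:
        raise ValueError("frames must be in increasing time order")
    d_b = float(
        np.linalg.norm(frame_t5.control_points[0] - frame_t0.control_points[0])
    )
    return WhiskerKinematics(base_displacement=d_b, base_speed=d_b / dt)


# ---------------------------------------------------------------------------
# Table-level (frames.csv) helpers


def curvature_at_base_table(frames: pd.DataFrame) -> np.ndarray:
    """Vectorised curvature kappa_3D(0) for every row of a frames table."""
    p0 = frames[["p0x", "p0y", "p0z"]].to_numpy(dtype=float)
    p1 = frames[["p1x", "p1y", "p1z"]].to_numpy(dtype=float)
    p2 = frames[["p2x", "p2y", "p2z"]].to_numpy(dtype=float)
    d1 = 2.0 * (p1 - p0)
    d2 = 2.0 * (p0 - 2.0 * p1 + p2)
    n1 = np.linalg.norm(d1, axis=1)
    kappa = np.zeros(len(frames))
    ok = n1 > _TANGENT_TOL
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} frame(s) with degenerate tangent; curvature 0",
            DegenerateCurveWarning,
            stacklevel=2,
        )
    cross = np.cross(d1[ok], np.broadcast_to(d2[ok], d1[ok].shape))
    kappa[ok] = np.linalg.norm(cross, axis=1) / n1[ok] ** 3
    return kappa


def rest_curvature_table(
    frames: pd.DataFrame, touches: pd.DataFrame
) -> pd.Series:
    """Per-(trial, whisker) resting curvature kappa_3D,0.

    Estimated as the median of kappa_3D(0) over all contact-free frames of
    the whisker in that trial; the median is robust to tracking noise.
    Frames inside any touch interval ``[onset, offset]`` (closed) of the same
    whisker are excluded.
    """
    kappa = curvature_at_base_table(frames)
    df = frames[["trial_id", "whisker_id", "time_ms"]].copy()
    df["kappa"] = kappa
    in_contact = np.zeros(len(df), dtype=bool)
    for (trial, wid), g in touches.groupby(["trial_id", "whisker_id"]):
        rows = np.flatnonzero(
            (df["trial_id"] == trial).to_numpy()
            & (df["whisker_id"] == wid).to_numpy()
        )
        t = df["time_ms"].to_numpy()[rows]
        mask = np.zeros(len(rows), dtype=bool)
        for onset, offset in zip(g["onset_ms"], g["offset_ms"]):
            mask |= (t >= onset) & (t <= offset)
        in_contact[rows[mask]] = True
    free = df[~in_contact]
    return free.groupby(["trial_id", "whisker_id"])["kappa"].median()


def touch_strengths_from_frames(
    frames: pd.DataFrame, touches: pd.DataFrame, window_ms: int = 5
) -> np.ndarray:
    """Signed touch strength for every row of a touches table.

    For each touch, the mean of ``kappa_3D(0) - kappa_rest`` over the
    ``window_ms`` frames following onset, with ``kappa_rest`` the
    per-(trial, whisker) contact-free median (:func:`rest_curvature_table`).
    """
    kappa = curvature_at_base_table(frames)
    rest = rest_curvature_table(frames, touches)
    lookup = pd.Series(
        kappa,
        index=pd.MultiIndex.from_frame(
            frames[["trial_id", "whisker_id", "time_ms"]]
        ),
    )
    strengths = np.empty(len(touches))
    for i, row in enumerate(touches.itertuples(index=False)):
        key = (row.trial_id, row.whisker_id)
        if key not in rest.index:
            raise ValueError(
                f"no rest-curvature estimate for whisker {row.whisker_id!r} "
                f"in trial {row.trial_id} (no contact-free frames)"
            )
        times = int(row.onset_ms) + np.arange(window_ms)
        try:
            vals = lookup.loc[
                [(row.trial_id, row.whisker_id, int(t)) for t in times]
            ].to_numpy()
        except KeyError:
            have = {
                t
                for (tr, w, t) in lookup.index
                if tr == row.trial_id and w == row.whisker_id
            }
            missing = [int(t) for t in times if int(t) not in have]
            raise ValueError(
                f"frames missing for times {missing} (ms) around touch at "
                f"{row.onset_ms} ms (trial {row.trial_id}, "
                f"whisker {row.whisker_id!r})"
            ) from None
        strengths[i] = float(np.mean(vals)) - float(rest.loc[key])
    return strengths
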