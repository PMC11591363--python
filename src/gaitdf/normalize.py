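"""Step extraction and 100-bin step-cycle normalization.

Steps of different durations are made comparable by resampling each
displacement curve onto a common cycle-percentage axis: an interpolating
cubic spline (not-a-knot boundary) is fitted to x(t) and y(t) independently
and evaluated at ``n_bins`` equally spaced times covering the whole step,
endpoints included.  Bin ``i`` (1-based) therefore sits at
``100 * (i - 1) / (n_bins - 1)`` percent of the step cycle.

By default each step is re-zeroed at its onset so curves encode
within-step displacement rather than arbitrary tunnel position
(``zeroing="none"`` keeps arena coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError, RangeError, StepExcludedError
from .io_tracks import PointTrack, StepInterval

#: Number of step-cycle bins; bin values are percent of cycle.
DEFAULT_BINS = 100

#: Annotation gaps of at most this many consecutive missing frames are
#: bridged by linear interpolation (12.5 ms at 240 fps); longer gaps
#: invalidate the step.
MAX_GAP_FRAMES = 3


@dataclass
class RawStepCurve:
    """Time-domain displacement samples of one step of one joint."""

    animal_id: str
    group: str
    day: int
    side: str
    joint: str
    step_id: int
    t: np.ndarray  # (n,) seconds from step onset, strictly increasing, t[0] = 0
    x: np.ndarray  # (n,) horizontal displacement
    y: np.ndarray  # (n,) vertical displacement
    fps: float
    units: str = "cm"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise InsufficientDataError("t, x, y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise InsufficientDataError("sample times must be strictly increasing")

    @property
    def keys(self) -> tuple:
        return (self.animal_id, self.group, self.day, self.side, self.joint, self.step_id)


@dataclass
class NormalizedStepCurve:
    """Displacement curve resampled to the common step-cycle axis."""

    animal_id: str
    group: str
    day: int
    side: str
    joint: str
    step_id: int
    x: np.ndarray  # (n_bins,) horizontal displacement per bin
    y: np.ndarray  # (n_bins,) vertical displacement per bin
    units: str = "cm"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise InsufficientDataError("x and y must be equal-length vectors")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise InsufficientDataError(f"non-finite values in curve {self.keys}")

    @property
    def n_bins(self) -> int:
        return self.x.size

    @property
    def keys(self) -> tuple:
        return (self.animal_id, self.group, self.day, self.side, self.joint, self.step_id)

    @property
    def stratum(self) -> tuple:
        """(side, joint, day) — the unit within which curves are compared."""
        return (self.side, self.joint, self.day)


def extract_step(
    track: PointTrack,
    interval: StepInterval,
    *,
    zeroing: str = "onset",
    max_gap: int = MAX_GAP_FRAMES,
) -> RawStepCurve:
    """Cut one step out of a track and re-time it from step onset.

    Annotation gaps of at most ``max_gap`` consecutive frames are filled by
    linear interpolation; a longer gap raises :class:`StepExcludedError`
    (the pipeline logs and skips such steps rather than aborting).
    """
    if zeroing not in ("onset", "none"):
        raise ValueError(f"unknown zeroing mode {zeroing!r}")
    if interval.start_frame < track.frames[0] or interval.end_frame > track.frames[-1]:
        raise RangeError(
            f"interval [{interval.start_frame}, {interval.end_frame}] outside track "
            f"{track.key} frames [{track.frames[0]}, {track.frames[-1]}]"
        )
    mask = (track.frames >= interval.start_frame) & (track.frames <= interval.end_frame)
    frames = track.frames[mask]
    gaps = np.diff(frames) - 1
    if gaps.size and gaps.max() > max_gap:
        i = int(np.argmax(gaps))
        raise StepExcludedError(
            f"step {interval.step_id} of {track.key}: {int(gaps[i])} consecutive "
            f"frames missing after frame {int(frames[i])} (limit {max_gap})"
        )
    full = np.arange(interval.start_frame, interval.end_frame + 1)
    x = np.interp(full, frames, track.xy[mask, 0])
    y = np.interp(full, frames, track.xy[mask, 1])
    if zeroing == "onset":
        x = x - x[0]
        y = y - y[0]
    t = (full - interval.start_frame) / track.fps
    return RawStepCurve(
        animal_id=track.animal_id,
        group=track.group,
        day=track.day,
        side=track.side,
        joint=track.joint,
        step_id=interval.step_id,
        t=t,
        x=x,
        y=y,
        fps=track.fps,
        units=track.units,
    )


def normalize_step(raw: RawStepCurve, n_bins: int = DEFAULT_BINS) -> NormalizedStepCurve:
    """Resample a step onto ``n_bins`` cycle-percentage bins by cubic spline.

    The spline interpolates (does not smooth); linear inputs are reproduced
    exactly and a curve already sampled at the bin times is a fixed point.
    """
    if raw.t.size < 4:
        raise InsufficientDataError(
            f"step {raw.keys} has {raw.t.size} samples; cubic spline needs >= 4"
        )
    bin_times = np.linspace(raw.t[0], raw.t[-1], n_bins)
    sx = CubicSpline(raw.t, raw.x, bc_type="not-a-knot")
    sy = CubicSpline(raw.t, raw.y, bc_type="not-a-knot")
    return NormalizedStepCurve(
        animal_id=raw.animal_id,
        group=raw.group,
        day=raw.day,
        side=raw.side,
        joint=raw.joint,
        step_id=raw.step_id,
        x=sx(bin_times),
        y=sy(bin_times),
        units=raw.units,
    )


def split_components(curve: NormalizedStepCurve) -> tuple[np.ndarray, np.ndarray]:
    """Return (VD, HD): the vertical (y) and horizontal (x) per-bin vectors."""
    return curve.y, curve.x


def curves_to_table(curves) -> pd.DataFrame:
    """Long-format table of normalized curves: one row per curve per bin."""
    rows = []
    for c in curves:
        n = c.n_bins
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": c.animal_id,
                    "group": c.group,
                    "day": c.day,
                    "side": c.side,
                    "joint": c.joint,
                    "step_id": c.step_id,
                    "bin": np.arange(1, n + 1),
                    "x": c.x,
                    "y": c.y,
                    "units": c.units,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["animal_id", "group", "day", "side", "joint", "step_id", "bin", "x", "y", "units"]
        )
    return pd.concat(rows, ignore_index=True)


def table_to_curves(df) -> list[NormalizedStepCurve]:
    """Inverse of :func:`curves_to_table`."""
    curves = []
    keys = ["animal_id", "group", "day", "side", "joint", "step_id"]
    for key, sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("bin")
        animal, group, day, side, joint, step = key
        curves.append(
            NormalizedStepCurve(
                animal_id=str(animal),
                group=str(group),
                day=int(day),
                side=str(side),
                joint=str(joint),
                step_id=int(step),
                x=sub["x"].to_numpy(dtype=np.float64),
                y=sub["y"].to_numpy(dtype=np.float64),
                units=str(sub["units"].iloc[0]) if "units" in sub else "cm",
            )
        )
    return curves


def write_normalized_curves(curves, path) -> None:
    curves_to_table(curves).to_csv(path, sep="\t", index=False)


def read_normalized_curves(path) -> list[NormalizedStepCurve]:
    return table_to_curves(pd.read_csv(path, sep="\t"))
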