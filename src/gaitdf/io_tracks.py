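"""Reading, writing and validation of trajectory annotations.

The pipeline consumes the export format of a frame-by-frame video annotation
tool: one row per (joint, frame) with pixel coordinates, plus a separate
table of step intervals (start/end frame of each selected step) and a
four-point calibration table per camera.  This module turns those flat
tables into typed containers and checks the structural invariants the rest
of the pipeline relies on.

Canonical track-table columns (comma-separated, UTF-8, ``.`` decimal)::

    animal_id, group, day, side, joint, frame, x, y, fps

A ``schema`` mapping lets renamed columns be ingested without rewriting the
file.  All coordinates are serialized with full ``repr`` precision so that a
write/read round trip is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: The five experimental groups of the study design.
GROUPS = (
    "control",
    "sham",
    "ischemia",
    "ischemia_nanopso",
    "pre_nanopso_ischemia",
)
SIDES = ("left", "right")
JOINTS = ("metatarsus", "ankle", "knee")
DAYS = (0, 3, 7)

TRACK_COLUMNS = (
    "animal_id",
    "group",
    "day",
    "side",
    "joint",
    "frame",
    "x",
    "y",
    "fps",
)
INTERVAL_COLUMNS = ("animal_id", "day", "side", "step_id", "start_frame", "end_frame")
CALIBRATION_COLUMNS = ("camera_id", "src_x", "src_y", "dst_x", "dst_y")


@dataclass
class PointTrack:
    """Frame-indexed 2-D trajectory of one joint of one limb in one session.

    ``units`` is ``"px"`` for raw video coordinates (origin top-left,
    y down) and ``"cm"`` after homographic correction to arena
    coordinates (y up).
    """

    animal_id: str
    group: str
    day: int
    side: str
    joint: str
    fps: float
    frames: np.ndarray  # (n,) int64, strictly increasing
    xy: np.ndarray  # (n, 2) float64
    units: str = "px"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if self.frames.ndim != 1 or self.xy.shape != (self.frames.size, 2):
            raise ValidationError("frames must be (n,), xy must be (n, 2)")
        if self.frames.size < 2:
            raise ValidationError(
                f"track {self.key} needs at least 2 frames, got {self.frames.size}"
            )
        if np.any(np.diff(self.frames) <= 0):
            raise ValidationError(f"frame indices of track {self.key} not strictly increasing")
        if np.any(self.frames < 0):
            raise ValidationError(f"negative frame index in track {self.key}")
        if self.units not in ("px", "cm"):
            raise ValidationError(f"unknown units {self.units!r}")

    @property
    def key(self) -> tuple:
        return (self.animal_id, self.day, self.side, self.joint)

    @property
    def session_key(self) -> tuple:
        """Key shared by all joints annotated in the same recording."""
        return (self.animal_id, self.day, self.side)


@dataclass(frozen=True)
class StepInterval:
    """Start/end frame of one selected step within a recording session."""

    animal_id: str
    day: int
    side: str
    step_id: int
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValidationError(
                f"step {self.step_id} of ({self.animal_id}, day {self.day}, "
                f"{self.side}): start_frame {self.start_frame} >= end_frame {self.end_frame}"
            )

    @property
    def session_key(self) -> tuple:
        return (self.animal_id, self.day, self.side)


@dataclass
class CalibrationSet:
    """Four pixel->arena point correspondences for one camera/session."""

    camera_id: str
    src: np.ndarray  # (4, 2) pixels
    dst: np.ndarray  # (4, 2) arena cm

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=np.float64)
        self.dst = np.asarray(self.dst, dtype=np.float64)


@dataclass
class GroupDataset:
    """All tracks, step intervals and calibrations of one experiment."""

    tracks: list[PointTrack] = field(default_factory=list)
    intervals: list[StepInterval] = field(default_factory=list)
    calibrations: dict[str, CalibrationSet] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def track_index(self) -> dict[tuple, PointTrack]:
        return {t.key: t for t in self.tracks}

    def intervals_for_session(self, session_key: tuple) -> list[StepInterval]:
        return [iv for iv in self.intervals if iv.session_key == session_key]


@dataclass
class ValidationReport:
    """Summary counts plus the list of invariant violations (empty = valid)."""

    group_animal_counts: dict[str, int]
    steps_per_session: dict[tuple, int]
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def _resolve_schema(
    df: pd.DataFrame, required: Sequence[str], schema: Mapping[str, str] | None
) -> pd.DataFrame:
    """Rename columns per ``schema`` (canonical -> actual) and check presence."""
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from input table")
    return df


def _numeric(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r} "
            f"at data row {row + 1}"
        )
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise ParseError(f"{path}: empty value in column {col!r} at data row {row + 1}")
    # re-parse with the correctly rounded strtod so serialization round-trips
    return pd.Series(df[col].to_numpy(dtype=np.float64), index=df.index)


def read_track_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[PointTrack]:
    """Read a long-format annotation table into a list of :class:`PointTrack`.

    Rows are grouped by (animal, day, side, joint) and sorted by frame, so
    the result does not depend on the row order of the file.  Duplicate
    (track, frame) rows are rejected.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df = _resolve_schema(df, TRACK_COLUMNS, schema)
    if df.empty:
        logger.warning("track table %s contains a header but no rows", path)
        return []
    for col in ("frame", "day"):
        df[col] = _numeric(df, col, path).astype(np.int64)
    for col in ("x", "y", "fps"):
        df[col] = _numeric(df, col, path)
    units = "px"
    if "units" in df.columns:
        uniq = df["units"].unique()
        if len(uniq) > 1:
            raise ValidationError(f"{path}: mixed units {sorted(uniq)}")
        units = str(uniq[0])

    tracks: list[PointTrack] = []
    for (animal, day, side, joint), sub in df.groupby(
        ["animal_id", "day", "side", "joint"], sort=True
    ):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        dup = frames[np.flatnonzero(np.diff(frames) == 0)]
        if dup.size:
            raise ValidationError(
                f"{path}: duplicate frame {int(dup[0])} for track "
                f"({animal}, day {day}, {side}, {joint})"
            )
        group_vals = sub["group"].unique()
        if len(group_vals) > 1:
            raise ValidationError(
                f"{path}: animal {animal} assigned to multiple groups {sorted(group_vals)}"
            )
        fps_vals = sub["fps"].unique()
        if len(fps_vals) > 1:
            raise ValidationError(f"{path}: inconsistent fps within track ({animal}, {joint})")
        tracks.append(
            PointTrack(
                animal_id=str(animal),
                group=str(group_vals[0]),
                day=int(day),
                side=str(side),
                joint=str(joint),
                fps=float(fps_vals[0]),
                frames=frames,
                xy=sub[["x", "y"]].to_numpy(),
                units=units,
            )
        )
    return tracks


def write_track_table(tracks: Iterable[PointTrack], path: str | Path) -> Path:
    """Serialize tracks to CSV with full float precision (round-trip exact)."""
    path = Path(path)
    rows = []
    for t in tracks:
        for f, (x, y) in zip(t.frames, t.xy):
            rows.append(
                (t.animal_id, t.group, t.day, t.side, t.joint, int(f), repr(float(x)),
                 repr(float(y)), repr(float(t.fps)), t.units)
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS + ("units",))
    df.to_csv(path, index=False)
    return path


def read_step_intervals(path: str | Path) -> list[StepInterval]:
    """Read and validate the step-interval table.

    Intervals of one recording session must be pairwise non-overlapping.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df = _resolve_schema(df, INTERVAL_COLUMNS, None)
    if df.empty:
        return []
    for col in ("day", "step_id", "start_frame", "end_frame"):
        df[col] = _numeric(df, col, path).astype(np.int64)
    intervals = [
        StepInterval(
            animal_id=str(r.animal_id),
            day=int(r.day),
            side=str(r.side),
            step_id=int(r.step_id),
            start_frame=int(r.start_frame),
            end_frame=int(r.end_frame),
        )
        for r in df.itertuples()
    ]
    _check_overlaps(intervals)
    return intervals


def _check_overlaps(intervals: Sequence[StepInterval]) -> None:
    by_session: dict[tuple, list[StepInterval]] = {}
    for iv in intervals:
        by_session.setdefault(iv.session_key, []).append(iv)
    for session, ivs in by_session.items():
        ivs = sorted(ivs, key=lambda iv: iv.start_frame)
        for a, b in zip(ivs, ivs[1:]):
            if b.start_frame < a.end_frame:
                raise ValidationError(
                    f"overlapping steps {a.step_id} and {b.step_id} in session {session}: "
                    f"[{a.start_frame}, {a.end_frame}] vs [{b.start_frame}, {b.end_frame}]"
                )


def write_step_intervals(intervals: Iterable[StepInterval], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(iv.animal_id, iv.day, iv.side, iv.step_id, iv.start_frame, iv.end_frame)
         for iv in intervals],
        columns=INTERVAL_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def read_calibration(path: str | Path) -> dict[str, CalibrationSet]:
    """Read per-camera 4-point correspondence tables."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df = _resolve_schema(df, CALIBRATION_COLUMNS, None)
    for col in ("src_x", "src_y", "dst_x", "dst_y"):
        df[col] = _numeric(df, col, path)
    out: dict[str, CalibrationSet] = {}
    for cam, sub in df.groupby("camera_id", sort=True):
        if len(sub) != 4:
            raise ValidationError(
                f"{path}: camera {cam} has {len(sub)} correspondences, expected 4"
            )
        out[str(cam)] = CalibrationSet(
            camera_id=str(cam),
            src=sub[["src_x", "src_y"]].to_numpy(),
            dst=sub[["dst_x", "dst_y"]].to_numpy(),
        )
    return out


def write_calibration(cals: Mapping[str, CalibrationSet], path: str | Path) -> Path:
    rows = []
    for cam in sorted(cals):
        c = cals[cam]
        for (sx, sy), (dx, dy) in zip(c.src, c.dst):
            rows.append((cam, repr(float(sx)), repr(float(sy)), repr(float(dx)), repr(float(dy))))
    pd.DataFrame(rows, columns=CALIBRATION_COLUMNS).to_csv(path, index=False)
    return Path(path)


def validate_dataset(ds: GroupDataset) -> ValidationReport:
    """Structural validation; pure (does not modify ``ds``).

    Checks that every step interval resolves to an existing in-range track
    for every joint of its session and that no animal appears in two groups.
    """
    violations: list[str] = []
    index = ds.track_index()

    animal_groups: dict[str, set[str]] = {}
    for t in ds.tracks:
        animal_groups.setdefault(t.animal_id, set()).add(t.group)
    for animal, groups in sorted(animal_groups.items()):
        if len(groups) > 1:
            violations.append(f"animal {animal} assigned to multiple groups {sorted(groups)}")

    sessions: dict[tuple, list[PointTrack]] = {}
    for t in ds.tracks:
        sessions.setdefault(t.session_key, []).append(t)

    steps_per_session: dict[tuple, int] = {}
    for iv in ds.intervals:
        steps_per_session[iv.session_key] = steps_per_session.get(iv.session_key, 0) + 1
        tracks = sessions.get(iv.session_key, [])
        if not tracks:
            violations.append(f"step {iv.step_id} references missing session {iv.session_key}")
            continue
        for t in tracks:
            if iv.start_frame < t.frames[0] or iv.end_frame > t.frames[-1]:
                violations.append(
                    f"step {iv.step_id} of session {iv.session_key} "
                    f"[{iv.start_frame}, {iv.end_frame}] outside track "
                    f"({t.joint}) frames [{t.frames[0]}, {t.frames[-1]}]"
                )
    try:
        _check_overlaps(ds.intervals)
    except ValidationError as exc:
        violations.append(str(exc))

    group_counts = {
        g: len({a for a, gs in animal_groups.items() if g in gs})
        for g in sorted({t.group for t in ds.tracks})
    }
    return ValidationReport(
        group_animal_counts=group_counts,
        steps_per_session=steps_per_session,
        violations=violations,
    )
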