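"""Reading and quality-filtering OpenFace-style frame-level tracking output.

OpenFace writes one CSV row per video frame with the tracker's confidence,
a success flag, gaze direction angles, head pose, and facial action-unit
(AU) intensities estimated by regression on the 0-5 FACS scale (columns
named like ``AU06_r``).  This module parses those tables into validated
frame tables, applies frame-level quality control, and reads the trial
annotation table that delimits the eyes-open trials.

The canonical in-memory representation of a track is a :class:`pandas.DataFrame`
with columns ``frame, timestamp, confidence, success, gaze_angle_x,
gaze_angle_y`` plus one normalised ``AUxx`` column per action unit.
:class:`FrameRecord` offers a typed per-frame view for callers that prefer
objects over tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "EmptyInputError",
    "QCConfig",
    "FrameRecord",
    "TrialAnnotation",
    "read_track",
    "write_track",
    "filter_frames",
    "retained_fraction",
    "to_records",
    "records_to_table",
    "read_annotations",
    "write_annotations",
]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "frame",
    "timestamp",
    "confidence",
    "success",
    "gaze_angle_x",
    "gaze_angle_y",
)

#: OpenFace regression AU columns, e.g. "AU06_r" or (tolerantly) "AU6_r".
_AU_COLUMN_RE = re.compile(r"^AU0*(\d{1,2})_r$")

AU_INTENSITY_MIN = 0.0
AU_INTENSITY_MAX = 5.0

GENDERS = ("M", "F")
CONDITIONS = ("blank", "own_face", "other_face")
TRIAL_INDICES = (1, 2, 3)


class FormatError(ValueError):
    """Input file violates the expected tabular format."""


class EmptyInputError(ValueError):
    """Input file contains no data rows."""


@dataclass(frozen=True)
class QCConfig:
    """Frame- and trial-level quality-control thresholds.

    Parameters
    ----------
    min_confidence
        Minimum tracker confidence (0-1) for a frame to be retained.
        The study protocol lists only behavioural exclusions (face covered,
        posture change out of frame); 0.75 is the conventional tracking
        cut and is exposed here rather than hard-coded.
    min_retained
        Minimum fraction of a trial's frames surviving QC before the trial
        is flagged excluded (mirrors subject-level instruction-violation
        exclusions, applied per trial because the trial is the unit of
        analysis).
    min_frames
        Minimum retained frame count for a usable trial (default 300,
        about 10 s at 30 fps).
    """

    min_confidence: float = 0.75
    min_retained: float = 0.5
    min_frames: int = 300

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError(f"min_confidence must be in [0, 1], got {self.min_confidence}")
        if not 0.0 <= self.min_retained <= 1.0:
            raise ValueError(f"min_retained must be in [0, 1], got {self.min_retained}")
        if self.min_frames < 1:
            raise ValueError(f"min_frames must be positive, got {self.min_frames}")


@dataclass
class FrameRecord:
    """One video frame's tracking state."""

    frame_index: int
    timestamp: float
    confidence: float
    success: bool
    gaze_angle_x: float
    gaze_angle_y: float
    au_intensity: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class TrialAnnotation:
    """Design labels and frame span of one eyes-open trial.

    ``frame_span`` is the half-open interval [start_frame, end_frame)
    within the source track; ``track`` names that source file.
    """

    subject_id: str
    gender: str
    condition: str
    trial_index: int
    start_frame: int
    end_frame: int
    track: str = ""

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.trial_index not in TRIAL_INDICES:
            raise ValueError(f"trial_index must be in {TRIAL_INDICES}, got {self.trial_index}")
        if self.end_frame <= self.start_frame:
            raise ValueError(
                f"frame_span [{self.start_frame}, {self.end_frame}) is empty"
            )

    @property
    def row_id(self) -> str:
        """Stable trial identifier used to align the two model blocks."""
        return f"{self.subject_id}|{self.condition}|t{self.trial_index}"


def normalise_au_code(column: str) -> str | None:
    """Map a regression AU column name to a canonical ``AUxx`` code.

    ``AU6_r`` and ``AU06_r`` both become ``AU06``; non-AU columns give None.
    """
    m = _AU_COLUMN_RE.match(column.strip())
    if m is None:
        return None
    return f"AU{int(m.group(1)):02d}"


def read_track(path: str | Path, config: QCConfig | None = None) -> pd.DataFrame:
    """Read one OpenFace-style CSV into a validated frame table.

    The header must contain ``frame, timestamp, confidence, success,
    gaze_angle_x, gaze_angle_y`` and at least one ``AUxx_r`` regression
    column.  Whitespace around header names is stripped (OpenFace emits
    leading spaces).  AU intensities are clamped to the [0, 5] regression
    scale and columns renamed to canonical ``AUxx`` codes.

    Raises
    ------
    EmptyInputError
        If the file holds no data rows.
    FormatError
        If a mandatory column is missing, no AU regression column is
        present, or frame indices are not strictly increasing.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: no data") from exc
    df.columns = [str(c).strip() for c in df.columns]
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")

    au_map = {c: normalise_au_code(c) for c in df.columns}
    au_cols = {c: code for c, code in au_map.items() if code is not None}
    if not au_cols:
        raise FormatError(f"{path}: no AU regression column (AUxx_r) found")

    out = df[list(MANDATORY_COLUMNS)].copy()
    out["frame"] = out["frame"].astype(np.int64)
    if (out["frame"] < 0).any():
        raise FormatError(f"{path}: negative frame index")
    if not (np.diff(out["frame"].to_numpy()) > 0).all():
        raise FormatError(f"{path}: frame indices not strictly increasing")
    out["timestamp"] = out["timestamp"].astype(float)
    out["confidence"] = out["confidence"].astype(float).clip(0.0, 1.0)
    out["success"] = out["success"].astype(float).astype(bool)
    for col in ("gaze_angle_x", "gaze_angle_y"):
        out[col] = out[col].astype(float)
    for src, code in sorted(au_cols.items(), key=lambda kv: kv[1]):
        out[code] = df[src].astype(float).clip(AU_INTENSITY_MIN, AU_INTENSITY_MAX)
    out.attrs["path"] = str(path)
    return out.reset_index(drop=True)


def write_track(table: pd.DataFrame, path: str | Path) -> None:
    """Write a frame table back to OpenFace-style CSV (``AUxx_r`` columns)."""
    out = table.copy()
    out["success"] = out["success"].astype(int)
    out = out.rename(columns={c: f"{c}_r" for c in au_columns(table)})
    out.to_csv(path, index=False, float_format="%.6f")


def au_columns(table: pd.DataFrame) -> list[str]:
    """Canonical AU columns present in a frame table, sorted by code."""
    return sorted(c for c in table.columns if re.fullmatch(r"AU\d{2}", str(c)))


def filter_frames(
    frames: pd.DataFrame | Sequence[FrameRecord],
    config: QCConfig | None = None,
) -> pd.DataFrame | list[FrameRecord]:
    """Retain frames with ``success`` true and confidence >= the QC cut.

    Accepts either a frame table or a sequence of :class:`FrameRecord`
    and returns the same kind.  May return an empty result; downstream
    trial assembly decides whether that excludes the trial.  Idempotent.
    """
    config = config or QCConfig()
    if isinstance(frames, pd.DataFrame):
        mask = frames["success"].astype(bool) & (
            frames["confidence"] >= config.min_confidence
        )
        kept = frames.loc[mask].reset_index(drop=True)
        kept.attrs.update(frames.attrs)
        n, k = len(frames), len(kept)
        logger.info(
            "filter_frames: %d read, %d retained (fraction %.3f)",
            n, k, (k / n) if n else 0.0,
        )
        return kept
    return [
        r for r in frames if r.success and r.confidence >= config.min_confidence
    ]


def retained_fraction(
    frames: pd.DataFrame | Sequence[FrameRecord],
    config: QCConfig | None = None,
) -> float:
    """Fraction of frames surviving :func:`filter_frames` (0.0 if empty input)."""
    n = len(frames)
    if n == 0:
        return 0.0
    return len(filter_frames(frames, config)) / n


def to_records(table: pd.DataFrame) -> list[FrameRecord]:
    """Typed per-frame view of a frame table."""
    aus = au_columns(table)
    records = []
    for row in table.itertuples(index=False):
        d = row._asdict()
        records.append(
            FrameRecord(
                frame_index=int(d["frame"]),
                timestamp=float(d["timestamp"]),
                confidence=float(d["confidence"]),
                success=bool(d["success"]),
                gaze_angle_x=float(d["gaze_angle_x"]),
                gaze_angle_y=float(d["gaze_angle_y"]),
                au_intensity={a: float(d[a]) for a in aus},
            )
        )
    return records


def records_to_table(records: Iterable[FrameRecord]) -> pd.DataFrame:
    """Inverse of :func:`to_records`."""
    records = list(records)
    aus = sorted({a for r in records for a in r.au_intensity})
    data = {
        "frame": [r.frame_index for r in records],
        "timestamp": [r.timestamp for r in records],
        "confidence": [r.confidence for r in records],
        "success": [r.success for r in records],
        "gaze_angle_x": [r.gaze_angle_x for r in records],
        "gaze_angle_y": [r.gaze_angle_y for r in records],
    }
    for a in aus:
        data[a] = [r.au_intensity.get(a, np.nan) for r in records]
    return pd.DataFrame(data)


ANNOTATION_COLUMNS = (
    "track",
    "subject_id",
    "gender",
    "condition",
    "trial_index",
    "start_frame",
    "end_frame",
)


def read_annotations(path: str | Path) -> list[TrialAnnotation]:
    """Read the trial annotation TSV (one row per eyes-open trial)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: no data") from exc
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns and c != "track"]
    if missing:
        raise FormatError(f"{path}: missing annotation column(s) {missing}")
    annotations = []
    for i, row in df.iterrows():
        try:
            annotations.append(
                TrialAnnotation(
                    subject_id=str(row["subject_id"]),
                    gender=str(row["gender"]),
                    condition=str(row["condition"]),
                    trial_index=int(row["trial_index"]),
                    start_frame=int(row["start_frame"]),
                    end_frame=int(row["end_frame"]),
                    track=str(row["track"]) if "track" in df.columns else "",
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    if not annotations:
        raise EmptyInputError(f"{path}: no annotations")
    return annotations


def write_annotations(annotations: Sequence[TrialAnnotation], path: str | Path) -> None:
    """Write annotations as TSV with the documented column order."""
    df = pd.DataFrame(
        [
            {
                "track": a.track,
                "subject_id": a.subject_id,
                "gender": a.gender,
                "condition": a.condition,
                "trial_index": a.trial_index,
                "start_frame": a.start_frame,
                "end_frame": a.end_frame,
            }
            for a in annotations
        ],
        columns=list(ANNOTATION_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)
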