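"""Per-trial behavioural covariates: AU expression ranges and gaze proportion.

Over a two-minute eyes-open trial of quiet sitting, action-unit intensity
traces consist of many small fluctuations punctuated by occasional
expression excursions.  The mean and standard deviation of such a trace
are dominated by the fluctuation "noise", so each AU is summarised by the
*range* of its intensity (max - min) over the trial.  The second covariate
family is the proportion of retained frames in which the gaze direction
points at the screen, operationalised as the gaze-angle magnitude falling
below an angular threshold (participants were free to look at or away from
the screen, which makes dwell time informative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .openface import FrameRecord, QCConfig, TrialAnnotation, au_columns, records_to_table

__all__ = [
    "InsufficientDataError",
    "GazeConfig",
    "TrialFeatureVector",
    "DEFAULT_AUS",
    "au_range",
    "gaze_on_screen_prop",
    "extract_trial_features",
    "features_table",
]


class InsufficientDataError(ValueError):
    """Too few frames (or values) to compute a trial feature."""


#: Default instrumental AU set: the 12 OpenFace regression AUs covering
#: every facial muscle implicated in the analysed latent structures
#: (brow raisers, brow lowerer / depressor glabellae, nose wrinkler,
#: cheek raiser, upper lip raiser, lip corner puller/depressor, dimpler
#: (buccinator), lip stretcher (risorius), chin raiser, lips part).
#: Together with the gaze proportion this yields 13 instrumental
#: variables.  The set is a documented reconstruction and fully
#: configurable -- see docs/methods.md.
DEFAULT_AUS: tuple[str, ...] = (
    "AU01",
    "AU02",
    "AU04",
    "AU06",
    "AU09",
    "AU10",
    "AU12",
    "AU14",
    "AU15",
    "AU17",
    "AU20",
    "AU25",
)


@dataclass(frozen=True)
class GazeConfig:
    """Angular criterion for "gaze fixed on the screen".

    ``threshold_rad`` is the maximum gaze-angle magnitude
    sqrt(gaze_angle_x**2 + gaze_angle_y**2) counted as on-screen.
    Default 10 degrees: the screen subtends roughly that angle at a
    typical webcam viewing distance; no numeric criterion is standard,
    so the threshold is a config knob recorded in output metadata.
    """

    threshold_rad: float = math.radians(10.0)

    def __post_init__(self) -> None:
        if self.threshold_rad <= 0:
            raise ValueError(f"threshold_rad must be > 0, got {self.threshold_rad}")


@dataclass
class TrialFeatureVector:
    """All instrumental covariates of one eyes-open trial."""

    subject_id: str
    gender: str
    condition: str
    trial_index: int
    gaze_on_screen_prop: float
    au_range: dict[str, float] = field(default_factory=dict)
    n_frames_used: int = 0
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def row_id(self) -> str:
        return f"{self.subject_id}|{self.condition}|t{self.trial_index}"


def au_range(intensities: Sequence[float] | np.ndarray) -> float:
    """Range (max - min) of an AU intensity series.

    Raises :class:`InsufficientDataError` on an empty series.
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("empty intensity series")
    return float(arr.max() - arr.min())


def gaze_on_screen_prop(
    frames: pd.DataFrame | Sequence[FrameRecord],
    config: GazeConfig | None = None,
) -> float:
    """Fraction of frames whose gaze-angle magnitude is within the threshold."""
    config = config or GazeConfig()
    if not isinstance(frames, pd.DataFrame):
        frames = records_to_table(list(frames))
    if len(frames) == 0:
        raise InsufficientDataError("no frames for gaze proportion")
    mag = np.hypot(
        frames["gaze_angle_x"].to_numpy(float),
        frames["gaze_angle_y"].to_numpy(float),
    )
    return float(np.mean(mag <= config.threshold_rad))


def extract_trial_features(
    frames: pd.DataFrame | Sequence[FrameRecord],
    annotation: TrialAnnotation,
    qc: QCConfig | None = None,
    gaze: GazeConfig | None = None,
    aus: Sequence[str] | None = None,
) -> TrialFeatureVector:
    """Reduce one QC-filtered trial to its instrumental feature vector.

    ``frames`` must already have passed :func:`facepls.openface.filter_frames`;
    the annotation's half-open ``[start_frame, end_frame)`` span selects the
    trial's frames by the ``frame`` column.  A trial with fewer than
    ``qc.min_frames`` retained frames is returned flagged ``excluded``
    rather than silently dropped, so block assembly can drop it from both
    blocks and report it.
    """
    qc = qc or QCConfig()
    gaze = gaze or GazeConfig()
    if not isinstance(frames, pd.DataFrame):
        frames = records_to_table(list(frames))
    aus = tuple(aus) if aus is not None else DEFAULT_AUS

    span = frames.loc[
        (frames["frame"] >= annotation.start_frame)
        & (frames["frame"] < annotation.end_frame)
    ]
    n_used = len(span)
    span_frames = annotation.end_frame - annotation.start_frame
    frac = n_used / span_frames
    base = dict(
        subject_id=annotation.subject_id,
        gender=annotation.gender,
        condition=annotation.condition,
        trial_index=annotation.trial_index,
    )
    reason = ""
    if n_used < qc.min_frames:
        reason = f"{n_used} retained frames < min_frames={qc.min_frames}"
    elif frac < qc.min_retained:
        reason = (
            f"retained fraction {frac:.3f} < min_retained={qc.min_retained}"
        )
    if reason:
        return TrialFeatureVector(
            **base,
            gaze_on_screen_prop=float("nan"),
            au_range={a: float("nan") for a in aus},
            n_frames_used=n_used,
            excluded=True,
            exclusion_reason=reason,
        )
    missing = [a for a in aus if a not in span.columns]
    if missing:
        raise InsufficientDataError(
            f"trial {annotation.row_id}: AU column(s) {missing} absent from track"
        )
    ranges = {a: au_range(span[a].to_numpy(float)) for a in aus}
    return TrialFeatureVector(
        **base,
        gaze_on_screen_prop=gaze_on_screen_prop(span, gaze),
        au_range=ranges,
        n_frames_used=n_used,
    )


def features_table(vectors: Sequence[TrialFeatureVector]) -> pd.DataFrame:
    """Trial-feature table, one row per trial.

    Columns: subject_id, gender, condition, trial_index,
    gaze_on_screen_prop, ``<AU>_range`` per configured AU,
    n_frames_used, excluded.
    """
    if not vectors:
        raise InsufficientDataError("no trial feature vectors")
    aus = sorted({a for v in vectors for a in v.au_range})
    rows = []
    for v in vectors:
        row = {
            "subject_id": v.subject_id,
            "gender": v.gender,
            "condition": v.condition,
            "trial_index": v.trial_index,
            "gaze_on_screen_prop": v.gaze_on_screen_prop,
        }
        for a in aus:
            row[f"{a}_range"] = v.au_range.get(a, float("nan"))
        row["n_frames_used"] = v.n_frames_used
        row["excluded"] = v.excluded
        rows.append(row)
    return pd.DataFrame(rows)
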