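"""Assembly of the two aligned matrices of the two-block PLS model.

Block No. 1 (instrumental) holds the measured behavioural covariates per
trial: the gaze-on-screen proportion followed by one expression-range
column per configured AU (13 columns with the default 12-AU set).
Block No. 2 (features) holds binary experimental-design indicators:
one column per subject ("individual specificity"), per gender, per
stimulus type (blank / own face / other face) and per trial position
(first / second / third) -- 26 columns for the full 18-subject cohort.
Redundant one-hot groups are kept on purpose: the decomposition tolerates
exact collinearity, and reference coding would hide levels the loadings
should display.

The model's objects are *trials* (18 subjects x 3 conditions x 3
eyes-open trials = 162 rows in the full design), which is what lets
trial-order indicators vary within the block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .openface import CONDITIONS, GENDERS, TRIAL_INDICES, TrialAnnotation

__all__ = [
    "AlignmentError",
    "LabellingError",
    "Block",
    "InstrumentalBlock",
    "FeatureBlock",
    "FeatureCoding",
    "encode_features",
    "align_blocks",
]


class AlignmentError(ValueError):
    """The two blocks cannot be brought to a common row ordering."""


class LabellingError(ValueError):
    """An annotation carries an unknown category level."""


@dataclass
class Block:
    """A rows-are-objects, columns-are-indicators data matrix."""

    matrix: np.ndarray
    row_ids: list[str]
    col_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("block matrix must be 2-D")
        n, p = self.matrix.shape
        if n != len(self.row_ids):
            raise ValueError(f"{n} rows but {len(self.row_ids)} row_ids")
        if p != len(self.col_names):
            raise ValueError(f"{p} columns but {len(self.col_names)} col_names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.row_ids, columns=self.col_names)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="row_id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Block":
        df = pd.read_csv(path, sep="\t", index_col="row_id")
        return cls(df.to_numpy(float), [str(i) for i in df.index], [str(c) for c in df.columns])


@dataclass
class InstrumentalBlock(Block):
    """Block No. 1: gaze proportion + AU ranges; no missing values allowed."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.isnan(self.matrix).any():
            raise ValueError("instrumental block contains missing values after assembly")


@dataclass
class FeatureBlock(Block):
    """Block No. 2: binary design indicators (entries strictly 0/1)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.isin(self.matrix, (0.0, 1.0)).all():
            raise ValueError("feature block entries must all be 0 or 1")


@dataclass(frozen=True)
class FeatureCoding:
    """One-hot coding scheme for the design-feature block.

    Column groups, in order: subjects (sorted), genders, stimulus
    conditions, trial positions.  For the study design of 18 subjects this
    gives 18 + 2 + 3 + 3 = 26 feature columns.
    """

    subjects: tuple[str, ...]
    genders: tuple[str, ...] = GENDERS
    conditions: tuple[str, ...] = CONDITIONS
    trial_indices: tuple[int, ...] = TRIAL_INDICES

    @property
    def col_names(self) -> list[str]:
        return (
            [f"subject={s}" for s in self.subjects]
            + [f"gender={g}" for g in self.genders]
            + [f"condition={c}" for c in self.conditions]
            + [f"trial={t}" for t in self.trial_indices]
        )

    def to_dict(self) -> dict:
        return {
            "subjects": list(self.subjects),
            "genders": list(self.genders),
            "conditions": list(self.conditions),
            "trial_indices": list(self.trial_indices),
        }


def encode_features(
    annotations: Sequence[TrialAnnotation],
    scheme: FeatureCoding | None = None,
) -> FeatureBlock:
    """One-hot encode the design labels of every trial into block No. 2.

    Each row carries exactly four ones: its subject, gender, stimulus
    type and trial-position indicator.

    Raises :class:`LabellingError` naming the offending row when an
    annotation's category level is absent from the coding scheme.
    """
    if not annotations:
        raise LabellingError("no annotations to encode")
    if scheme is None:
        scheme = FeatureCoding(subjects=tuple(sorted({a.subject_id for a in annotations})))
    cols = scheme.col_names
    index = {name: j for j, name in enumerate(cols)}
    mat = np.zeros((len(annotations), len(cols)))
    row_ids = []
    for i, a in enumerate(annotations):
        for name in (
            f"subject={a.subject_id}",
            f"gender={a.gender}",
            f"condition={a.condition}",
            f"trial={a.trial_index}",
        ):
            if name not in index:
                raise LabellingError(
                    f"row {i} ({a.subject_id}): level {name!r} not in coding scheme"
                )
            mat[i, index[name]] = 1.0
        row_ids.append(a.row_id)
    if len(set(row_ids)) != len(row_ids):
        raise LabellingError("duplicate trial identifiers in annotations")
    return FeatureBlock(mat, row_ids, cols)


def align_blocks(
    features: pd.DataFrame,
    encoded: FeatureBlock,
    aus: Sequence[str] | None = None,
) -> tuple[InstrumentalBlock, FeatureBlock]:
    """Build block No. 1 from the trial-feature table and align it with block No. 2.

    Excluded trials are removed from *both* blocks row-wise, so the
    paired matrices stay congruent.  Instrumental column order is the
    gaze proportion followed by the AU ranges.

    Raises :class:`AlignmentError` if no trial survives in both blocks.
    """
    feats = features.copy()
    feats["row_id"] = (
        feats["subject_id"].astype(str)
        + "|"
        + feats["condition"].astype(str)
        + "|t"
        + feats["trial_index"].astype(int).astype(str)
    )
    if feats["row_id"].duplicated().any():
        raise AlignmentError("duplicate trial identifiers in feature table")
    feats = feats.set_index("row_id")

    if aus is None:
        aus = sorted(
            c[: -len("_range")] for c in feats.columns if str(c).endswith("_range")
        )
    inst_cols = ["gaze_on_screen_prop"] + [f"{a}_range" for a in aus]
    missing = [c for c in inst_cols if c not in feats.columns]
    if missing:
        raise AlignmentError(f"feature table lacks instrumental column(s) {missing}")

    usable = feats.loc[~feats["excluded"].astype(bool)] if "excluded" in feats else feats
    keep = [rid for rid in encoded.row_ids if rid in usable.index]
    if not keep:
        raise AlignmentError("no common non-excluded trials between the two blocks")

    inst = usable.loc[keep, inst_cols].to_numpy(float)
    sel = [encoded.row_ids.index(rid) for rid in keep]
    feat = encoded.matrix[sel]

    b1 = InstrumentalBlock(
        inst, list(keep), ["gaze_on_screen_prop"] + [f"{a}_range" for a in aus]
    )
    b2 = FeatureBlock(feat, list(keep), list(encoded.col_names))
    if b1.row_ids != b2.row_ids:
        raise AlignmentError("row identifiers differ after alignment")
    return b1, b2


def write_coding_sidecar(scheme: FeatureCoding, path: str | Path) -> None:
    """JSON record of the one-hot coding scheme used for block No. 2."""
    Path(path).write_text(json.dumps(scheme.to_dict(), indent=2, sort_keys=True) + "\n")
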