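"""End-to-end pipeline: tracking CSVs -> trial features -> blocks -> 2B-PLS.

Stages are the documented TSV/JSON interfaces, so each can be run and
tested independently; :func:`run_pipeline` chains them and writes every
intermediate product plus a JSON run report.  Any stage failure is
re-raised as :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import blocks as blocks_mod
from . import openface
from .config import ConfigError, RunConfig
from .features import extract_trial_features, features_table
from .pls import PLS2B, PLS2BResults
from .simulate import SyntheticCohort

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "fit_cohort"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    """Everything a finished run produced, in memory."""

    report: dict
    features: pd.DataFrame
    b1: blocks_mod.InstrumentalBlock
    b2: blocks_mod.FeatureBlock
    results: PLS2BResults


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


@_stage("ingest")
def _ingest(config: RunConfig) -> tuple[list, pd.DataFrame]:
    annotations = openface.read_annotations(config.annotation_file)
    vectors = []
    cache: dict[str, pd.DataFrame] = {}
    for a in annotations:
        track = a.track or ""
        if not track:
            raise openface.FormatError(f"annotation {a.row_id} names no track file")
        if track not in cache:
            raw = openface.read_track(config.input_dir / track, config.qc)
            kept = openface.filter_frames(raw, config.qc)
            frac = len(kept) / len(raw) if len(raw) else 0.0
            logger.info(
                "track %s: %d frames read, %d retained (fraction %.3f)",
                track, len(raw), len(kept), frac,
            )
            cache[track] = kept
        vectors.append(
            extract_trial_features(cache[track], a, config.qc, config.gaze, config.aus)
        )
    return annotations, features_table(vectors)


@_stage("blocks")
def _build_blocks(config: RunConfig, annotations, features):
    scheme = blocks_mod.FeatureCoding(
        subjects=tuple(sorted({a.subject_id for a in annotations}))
    )
    encoded = blocks_mod.encode_features(annotations, scheme)
    b1, b2 = blocks_mod.align_blocks(features, encoded, config.aus)
    return scheme, b1, b2


@_stage("fit")
def _fit(config: RunConfig, b1, b2) -> PLS2BResults:
    return PLS2B(b1, b2, mode=config.preprocessing).fit()


@_stage("report")
def _write_outputs(config, scheme, features, b1, b2, results) -> dict:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    features.to_csv(out / "features.tsv", sep="\t", index=False, float_format="%.10g")
    b1.to_tsv(out / "block1.tsv")
    b2.to_tsv(out / "block2.tsv")
    blocks_mod.write_coding_sidecar(scheme, out / "coding.json")
    results.save(out / "model")
    for pair in config.pairs:
        tab = results.loadings_table(tuple(pair), config.alpha)
        tab.to_csv(
            out / f"loadings_s{pair[0]}_s{pair[1]}.tsv",
            sep="\t", index=False, float_format="%.10g",
        )
    if config.n_permutations > 0:
        p1, p2 = results.permutation_loading_pvalues(config.n_permutations, config.seed)
        for mat, names, fname in (
            (p1, b1.col_names, "perm_pvalues_b1.tsv"),
            (p2, b2.col_names, "perm_pvalues_b2.tsv"),
        ):
            pd.DataFrame(
                mat, index=names, columns=[f"s{i + 1}" for i in range(results.k)]
            ).to_csv(out / fname, sep="\t", index_label="name", float_format="%.10g")

    n_excluded = int(features["excluded"].sum())
    report = {
        "trials_annotated": int(len(features)),
        "trials_excluded": n_excluded,
        "excluded_row_ids": sorted(
            f"{r.subject_id}|{r.condition}|t{int(r.trial_index)}"
            for r in features[features["excluded"]].itertuples()
        ),
        "block1_shape": list(b1.shape),
        "block2_shape": list(b2.shape),
        "n_latent_structures": results.k,
        "variance_share": results.variance_share.tolist(),
        "critical_r": results.critical_r(config.alpha),
        "alpha": config.alpha,
        "seed": config.seed,
        "config": config.settings_dict(),
        "config_hash": config.config_hash(),
        "complete": True,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages: read -> filter -> features -> blocks -> fit -> reports.

    The configuration is validated before any compute; a missing input
    path fails immediately with :class:`~facepls.config.ConfigError`.
    """
    config.validate()
    annotations, features = _ingest(config)
    scheme, b1, b2 = _build_blocks(config, annotations, features)
    results = _fit(config, b1, b2)
    try:
        report = _write_outputs(config, scheme, features, b1, b2, results)
    except PipelineError:
        out = Path(config.output_dir)
        if out.is_dir():
            (out / "report.json").write_text(
                json.dumps({"complete": False}, indent=2) + "\n"
            )
        raise
    return PipelineResult(report, features, b1, b2, results)


def fit_cohort(
    cohort: SyntheticCohort,
    qc: openface.QCConfig | None = None,
    gaze=None,
    aus: tuple[str, ...] | None = None,
    mode: str = "center_scale",
) -> PipelineResult:
    """In-memory pipeline over a generated cohort (no file round trip).

    Applies the same QC filtering, feature extraction, block assembly and
    fit as :func:`run_pipeline`; used for simulation studies where disk
    I/O would dominate.
    """
    qc = qc or openface.QCConfig()
    aus = aus or cohort.effects.aus
    vectors = []
    for trial in cohort.trials:
        kept = openface.filter_frames(trial.frames, qc)
        vectors.append(extract_trial_features(kept, trial.annotation, qc, gaze, aus))
    features = features_table(vectors)
    scheme = blocks_mod.FeatureCoding(
        subjects=tuple(sorted({a.subject_id for a in cohort.annotations}))
    )
    encoded = blocks_mod.encode_features(cohort.annotations, scheme)
    b1, b2 = blocks_mod.align_blocks(features, encoded, aus)
    results = PLS2B(b1, b2, mode=mode).fit()
    report = {
        "trials_annotated": int(len(features)),
        "trials_excluded": int(features["excluded"].sum()),
        "block1_shape": list(b1.shape),
        "block2_shape": list(b2.shape),
        "n_latent_structures": results.k,
    }
    return PipelineResult(report, features, b1, b2, results)
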