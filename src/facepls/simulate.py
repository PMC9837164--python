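"""Synthetic cohort generator with planted design effects.

The study's raw face videos are not deposited, so every pipeline stage is
exercised on synthetic frame-level tracking tables that emulate the study
design: 18 subjects (8 men, 10 women), three stimulus conditions (blank
screen, own face, other face), three two-minute eyes-open trials per
condition.  The blank condition always comes first; half the subjects
then see their own face before the unfamiliar one, half the reverse.

Each AU intensity trace is built as

    baseline + subject offset + AR(1) frame noise + expression events,

clamped to the 0-5 regression scale.  Frame noise is AR(1) (lag-1
correlation 0.9 by default) because consecutive tracker outputs are
strongly autocorrelated; white noise would make the per-trial range grow
degenerately with trial length.  Expression events are short smooth bumps
(0.5-2 s Hann windows) whose amplitude carries the planted effects: the
analysis statistic is the *range* of the trace, which is driven by
excursions, not by baseline shifts.

Planted effects (directions mirror the latent-structure narrative the
pipeline should recover; magnitudes are generator defaults, calibrated so
the leading structure explains roughly half the total variance):

* gender x first-trial: buccinator/risorius (AU14/AU20) excursions larger
  in women and smaller in men on every first trial, with the opposite
  push on gaze dwell;
* stimulus type: own face raises cheek-raiser (AU06) excursions and gaze
  dwell, blank screen lowers both, other face is neutral;
* third trial: chin raiser (AU17) and brow lowerer / depressor glabellae
  (AU04) up, inner brow raiser (AU01) down, lips part (AU25) up;
* subject random effects on baseline and excursion amplitude
  ("individual specificity").

Gaze is simulated as dwell segments (default 1 s) that are on-screen with
a condition-dependent probability; on-screen frames get small gaze angles,
off-screen frames a magnitude well outside the fixation threshold.

:func:`generate_blocks` is the block-level shortcut for statistical
tests: a rank-1 shared latent score propagated into two Gaussian-noise
blocks at a chosen signal-to-noise ratio.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .blocks import Block
from .features import DEFAULT_AUS
from .openface import CONDITIONS, TrialAnnotation, write_annotations, write_track

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "SimTrial",
    "SyntheticCohort",
    "generate_cohort",
    "generate_blocks",
]


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the simulated cohort (defaults = the study)."""

    n_subjects: int = 18
    n_men: int = 8
    n_women: int = 10
    conditions: tuple[str, ...] = CONDITIONS
    trials_per_condition: int = 3
    trial_seconds: float = 120.0
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_men + self.n_women != self.n_subjects:
            raise ValueError(
                f"n_men + n_women = {self.n_men + self.n_women} != n_subjects = {self.n_subjects}"
            )
        for name in ("n_subjects", "n_men", "n_women", "trials_per_condition"):
            if getattr(self, name) < 1 and name not in ("n_men", "n_women"):
                raise ValueError(f"{name} must be positive")
        if self.n_men < 0 or self.n_women < 0:
            raise ValueError("subject counts must be non-negative")
        if self.trial_seconds <= 0 or self.fps <= 0:
            raise ValueError("trial_seconds and fps must be positive")

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_seconds * self.fps))

    @property
    def n_trials(self) -> int:
        return self.n_subjects * len(self.conditions) * self.trials_per_condition


@dataclass(frozen=True)
class EffectSpec:
    """Planted effect magnitudes and noise levels (AU intensity units).

    All ``*_delta`` terms act on the amplitude of expression events and
    therefore, to first order, on the per-trial range statistic.
    """

    aus: tuple[str, ...] = DEFAULT_AUS
    au_baseline: float = 0.8
    noise_sd: float = 0.05
    ar1_rho: float = 0.9
    amp_base: float = 0.6
    amp_jitter: float = 0.15          # events drawn as amp * U(1 - jitter, 1)
    event_rate_per_s: float = 0.05
    event_duration_s: tuple[float, float] = (0.5, 2.0)
    subject_baseline_sd: float = 0.10
    subject_amp_sd: float = 0.15
    # gender x first-trial pattern (women +, men -): strongest on
    # buccinator/risorius, with a weaker broad component on every other AU
    # so the leading structure is a "general" axis rather than a two-variable one
    gender_first_trial_aus: tuple[str, ...] = ("AU14", "AU20")
    gender_first_trial_delta: float = 1.0
    gender_first_trial_broad_delta: float = 0.3
    gender_first_trial_gaze: float = 0.18  # men +, women - on first trials
    # stimulus-type pattern on the cheek raiser and gaze dwell
    stimulus_au: str = "AU06"
    stimulus_delta: float = 0.35           # own face +, blank -, other 0
    stimulus_gaze: float = 0.10
    # third-trial pattern
    third_trial_deltas: tuple[tuple[str, float], ...] = (
        ("AU17", 0.25),
        ("AU04", 0.25),
        ("AU01", -0.25),
        ("AU25", 0.25),
    )
    # gaze dwell model
    gaze_dwell_base: float = 0.65
    gaze_segment_frames: int = 30
    gaze_on_sd: float = 0.05               # radians, per axis, on-screen
    gaze_off_magnitude: float = 0.35       # radians, off-screen
    # tracker quality model
    confidence_mean: float = 0.92
    confidence_sd: float = 0.04
    low_confidence_prob: float = 0.02
    tracking_failure_prob: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 <= self.gaze_dwell_base <= 1.0:
            raise ValueError("gaze_dwell_base must be a probability")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.gaze_segment_frames < 1:
            raise ValueError("gaze_segment_frames must be >= 1")

    @classmethod
    def zero(cls, **overrides) -> "EffectSpec":
        """All planted effects and subject heterogeneity switched off."""
        return cls(
            gender_first_trial_delta=0.0,
            gender_first_trial_broad_delta=0.0,
            gender_first_trial_gaze=0.0,
            stimulus_delta=0.0,
            stimulus_gaze=0.0,
            third_trial_deltas=(),
            subject_baseline_sd=0.0,
            subject_amp_sd=0.0,
            **overrides,
        )

    def event_amplitude(self, au: str, gender: str, condition: str, trial_index: int) -> float:
        """Planted mean excursion amplitude for one AU in one trial (pre-noise)."""
        amp = self.amp_base
        if trial_index == 1:
            d = (
                self.gender_first_trial_delta
                if au in self.gender_first_trial_aus
                else self.gender_first_trial_broad_delta
            )
            amp += d * (1.0 if gender == "F" else -1.0)
        if au == self.stimulus_au:
            if condition == "own_face":
                amp += self.stimulus_delta
            elif condition == "blank":
                amp -= self.stimulus_delta
        for a, d in self.third_trial_deltas:
            if au == a and trial_index == 3:
                amp += d
        return max(amp, 0.05)

    def dwell_probability(self, gender: str, condition: str, trial_index: int) -> float:
        """Planted probability that a gaze dwell segment is on-screen."""
        p = self.gaze_dwell_base
        if condition == "own_face":
            p += self.stimulus_gaze
        elif condition == "blank":
            p -= self.stimulus_gaze
        if trial_index == 1:
            p += self.gender_first_trial_gaze * (1.0 if gender == "M" else -1.0)
        return float(np.clip(p, 0.02, 0.98))


@dataclass
class SimTrial:
    """One generated eyes-open trial: its annotation, frames, and ground truth."""

    annotation: TrialAnnotation
    frames: pd.DataFrame
    truth: dict


@dataclass
class SyntheticCohort:
    """A fully generated cohort; regeneration is determined by spec + effects + seed."""

    spec: CohortSpec
    effects: EffectSpec
    trials: list[SimTrial]

    @property
    def annotations(self) -> list[TrialAnnotation]:
        return [t.annotation for t in self.trials]

    @property
    def ground_truth(self) -> dict:
        payload = {
            "spec": asdict(self.spec),
            "effects": _effects_dict(self.effects),
            "trials": [t.truth for t in self.trials],
        }
        payload["spec_hash"] = _spec_hash(self.spec, self.effects)
        return payload

    def write(self, directory: str | Path) -> Path:
        """Write one OpenFace-style CSV per trial, the annotation TSV, and ground truth."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        annotations = []
        for t in self.trials:
            a = t.annotation
            name = f"{a.subject_id}_{a.condition}_t{a.trial_index}.csv"
            write_track(t.frames, d / name)
            annotations.append(replace(a, track=name))
        write_annotations(annotations, d / "annotations.tsv")
        (d / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=2, sort_keys=True) + "\n"
        )
        return d


def _effects_dict(effects: EffectSpec) -> dict:
    d = asdict(effects)
    d["third_trial_deltas"] = [list(x) for x in effects.third_trial_deltas]
    return d


def _spec_hash(spec: CohortSpec, effects: EffectSpec) -> str:
    blob = json.dumps({"spec": asdict(spec), "effects": _effects_dict(effects)},
                      sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _subject_labels(spec: CohortSpec) -> list[tuple[str, str]]:
    """(subject_id, gender) pairs; men first then women, ids S01..Snn."""
    genders = ["M"] * spec.n_men + ["F"] * spec.n_women
    return [(f"S{i + 1:02d}", g) for i, g in enumerate(genders)]


def _condition_order(spec: CohortSpec, subject_index: int) -> list[str]:
    """Blank first; own/other face order counterbalanced across subjects."""
    rest = [c for c in spec.conditions if c != "blank"]
    if "blank" not in spec.conditions:
        return list(spec.conditions)
    if subject_index % 2 == 1:
        rest = rest[::-1]
    return ["blank"] + rest


def _ar1(rng: np.random.Generator, n: int, cols: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise, marginal sd ``sd``, lag-1 correlation ``rho``."""
    if sd == 0.0:
        return np.zeros((n, cols))
    innov = rng.standard_normal((n, cols)) * sd * np.sqrt(1.0 - rho**2)
    innov[0] = rng.standard_normal(cols) * sd  # stationary start
    return signal.lfilter([1.0], [1.0, -rho], innov, axis=0)


def _generate_trial(
    rng: np.random.Generator,
    spec: CohortSpec,
    effects: EffectSpec,
    subject_id: str,
    gender: str,
    condition: str,
    trial_index: int,
    subj_baseline: np.ndarray,
    subj_amp: np.ndarray,
) -> SimTrial:
    n = spec.frames_per_trial
    aus = effects.aus
    t = np.arange(n) / spec.fps

    series = np.full((n, len(aus)), effects.au_baseline) + subj_baseline
    series += _ar1(rng, n, len(aus), effects.noise_sd, effects.ar1_rho)

    amps = {}
    expected_rate = effects.event_rate_per_s * spec.trial_seconds
    for j, au in enumerate(aus):
        amp = effects.event_amplitude(au, gender, condition, trial_index) + subj_amp[j]
        amp = max(amp, 0.05)
        amps[au] = amp
        n_events = max(1, int(rng.poisson(expected_rate)))
        for _ in range(n_events):
            dur = rng.uniform(*effects.event_duration_s)
            width = max(3, int(round(dur * spec.fps)))
            start = int(rng.integers(0, max(1, n - width)))
            bump_amp = amp * rng.uniform(1.0 - effects.amp_jitter, 1.0)
            series[start : start + width, j] += bump_amp * np.hanning(width)
    series = np.clip(series, 0.0, 5.0)

    # gaze: dwell segments, each fully on- or off-screen
    dwell_p = effects.dwell_probability(gender, condition, trial_index)
    n_seg = int(np.ceil(n / effects.gaze_segment_frames))
    seg_on = rng.random(n_seg) < dwell_p
    on = np.repeat(seg_on, effects.gaze_segment_frames)[:n]
    gx = rng.standard_normal(n) * effects.gaze_on_sd
    gy = rng.standard_normal(n) * effects.gaze_on_sd
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    off_mag = effects.gaze_off_magnitude * (1.0 + 0.1 * rng.standard_normal(n))
    gx = np.where(on, gx, off_mag * np.cos(theta))
    gy = np.where(on, gy, off_mag * np.sin(theta))

    conf = np.clip(
        effects.confidence_mean + effects.confidence_sd * rng.standard_normal(n), 0.0, 1.0
    )
    low = rng.random(n) < effects.low_confidence_prob
    conf[low] = rng.uniform(0.2, 0.6, int(low.sum()))
    success = rng.random(n) >= effects.tracking_failure_prob

    frames = pd.DataFrame(
        {
            "frame": np.arange(n, dtype=np.int64),
            "timestamp": t,
            "confidence": conf,
            "success": success,
            "gaze_angle_x": gx,
            "gaze_angle_y": gy,
        }
    )
    for j, au in enumerate(aus):
        frames[au] = series[:, j]

    annotation = TrialAnnotation(
        subject_id=subject_id,
        gender=gender,
        condition=condition,
        trial_index=trial_index,
        start_frame=0,
        end_frame=n,
    )
    truth = {
        "row_id": annotation.row_id,
        "subject_id": subject_id,
        "gender": gender,
        "condition": condition,
        "trial_index": trial_index,
        "event_amplitude": {au: float(a) for au, a in amps.items()},
        "dwell_probability": dwell_p,
    }
    return SimTrial(annotation, frames, truth)


def generate_cohort(
    spec: CohortSpec | None = None, effects: EffectSpec | None = None
) -> SyntheticCohort:
    """Generate the full synthetic cohort deterministically from ``spec.seed``.

    Trials are generated subject by subject (blank first, own/other-face
    order counterbalanced), so a fixed seed reproduces the cohort exactly,
    byte for byte once written.
    """
    spec = spec or CohortSpec()
    effects = effects or EffectSpec()
    rng = np.random.default_rng(spec.seed)
    subjects = _subject_labels(spec)
    aus = effects.aus

    trials: list[SimTrial] = []
    for si, (sid, gender) in enumerate(subjects):
        subj_baseline = rng.standard_normal(len(aus)) * effects.subject_baseline_sd
        subj_amp = rng.standard_normal(len(aus)) * effects.subject_amp_sd
        for condition in _condition_order(spec, si):
            for trial_index in range(1, spec.trials_per_condition + 1):
                trials.append(
                    _generate_trial(
                        rng, spec, effects, sid, gender, condition, trial_index,
                        subj_baseline, subj_amp,
                    )
                )
    return SyntheticCohort(spec, effects, trials)


def generate_blocks(
    n: int = 162,
    p1: int = 13,
    p2: int = 26,
    planted: tuple[np.ndarray, np.ndarray] | None = None,
    snr: float = 2.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[Block, Block, dict]:
    """Rank-1 planted-structure block pair for statistical tests.

    A shared standard-normal latent score ``t`` is propagated into both
    blocks along planted unit weight vectors ``u1`` (p1) and ``u2`` (p2),
    on top of unit-variance Gaussian noise:

        B1 = snr * t u1' + E1,   B2 = snr * t u2' + E2.

    ``snr`` is the per-element ratio of signal to noise standard
    deviation; at the default 2.0 the planted cross-covariance direction
    dominates the noise operator norm by roughly a factor of five at
    n = 162, p1 = 13, p2 = 26.  ``snr = 0`` yields a pure null pair.
    """
    if n < 10:
        raise ValueError(f"need n >= 10 objects, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if planted is None:
        u1 = rng.standard_normal(p1)
        u2 = rng.standard_normal(p2)
    else:
        u1, u2 = (np.asarray(v, dtype=float) for v in planted)
        if u1.shape != (p1,) or u2.shape != (p2,):
            raise ValueError("planted vectors do not match (p1,), (p2,)")
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    t = rng.standard_normal(n)
    x1 = snr * np.outer(t, u1) + rng.standard_normal((n, p1))
    x2 = snr * np.outer(t, u2) + rng.standard_normal((n, p2))
    rows = [f"obj{i:04d}" for i in range(n)]
    b1 = Block(x1, rows, [f"b1_v{j:02d}" for j in range(p1)])
    b2 = Block(x2, rows, [f"b2_v{j:02d}" for j in range(p2)])
    truth = {"u1": u1, "u2": u2, "latent": t, "snr": float(snr)}
    return b1, b2, truth
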