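"""Per-trial covariates: AU ranges and the gaze-on-screen proportion."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from facepls.features import (
    DEFAULT_AUS,
    GazeConfig,
    InsufficientDataError,
    au_range,
    extract_trial_features,
    features_table,
    gaze_on_screen_prop,
)
from facepls.openface import QCConfig, TrialAnnotation, filter_frames
from facepls.simulate import CohortSpec, EffectSpec, generate_cohort


class TestAuRange:
    @pytest.mark.parametrize(
        "series,expected",
        [([0.2, 0.2, 0.2], 0.0), ([0.1, 0.5, 0.3], pytest.approx(0.4))],
    )
    def test_definition(self, series, expected):
        assert au_range(series) == expected

    def test_spike_series_against_brute_force(self):
        # 1000-frame series: flat baseline 1.0 with a single spike to 3.2
        series = np.full(1000, 1.0)
        series[437] = 3.2
        brute = max(series) - min(series)  # independent linear scan
        assert au_range(series) == pytest.approx(brute) == pytest.approx(2.2)

    def test_empty_series_is_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            au_range([])

    @given(
        xs=st.lists(st.floats(-10, 10), min_size=1, max_size=50),
        shift=st.floats(-5, 5),
        scale=st.floats(0, 4),
    )
    def test_translation_invariant_and_scale_equivariant(self, xs, shift, scale):
        arr = np.asarray(xs)
        base = au_range(arr)
        assert au_range(arr + shift) == pytest.approx(base, abs=1e-9)
        assert au_range(arr * scale) == pytest.approx(scale * base, rel=1e-9, abs=1e-9)


def _gaze_frames(mags):
    n = len(mags)
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "timestamp": np.arange(n) / 30.0,
            "confidence": 0.95,
            "success": True,
            "gaze_angle_x": mags,
            "gaze_angle_y": 0.0,
            "AU06": 1.0,
        }
    )


class TestGazeProportion:
    def test_all_gaze_centred_gives_one(self):
        assert gaze_on_screen_prop(_gaze_frames([0.0] * 8)) == 1.0

    def test_counting(self):
        mags = [0.01] * 4 + [0.5] * 6
        assert gaze_on_screen_prop(_gaze_frames(mags)) == pytest.approx(0.4)

    def test_empty_is_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            gaze_on_screen_prop(_gaze_frames([]))

    @given(thresholds=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_monotone_in_threshold(self, thresholds):
        mags = np.linspace(0, 0.8, 37)
        props = [
            gaze_on_screen_prop(_gaze_frames(mags), GazeConfig(threshold_rad=t))
            for t in sorted(thresholds)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(props, props[1:]))

    def test_binomial_recovery_of_generator_dwell_probability(self):
        # per-frame independent dwell (segment length 1), 6000 frames at p = 0.7
        spec = CohortSpec(n_subjects=1, n_men=0, n_women=1, trials_per_condition=1,
                          trial_seconds=200.0, fps=30.0, seed=3)
        eff = EffectSpec.zero(gaze_dwell_base=0.7, gaze_segment_frames=1)
        cohort = generate_cohort(spec, eff)
        trial = cohort.trials[0]
        prop = gaze_on_screen_prop(trial.frames, GazeConfig(threshold_rad=math.radians(10)))
        assert prop == pytest.approx(0.7, abs=0.02)


class TestExtractTrialFeatures:
    def test_thirteen_instrumental_values(self, tiny_cohort):
        trial = tiny_cohort.trials[0]
        qc = QCConfig(min_frames=50)
        vec = extract_trial_features(
            filter_frames(trial.frames, qc), trial.annotation, qc, aus=DEFAULT_AUS
        )
        assert not vec.excluded
        assert len(vec.au_range) == 12
        assert 0.0 <= vec.gaze_on_screen_prop <= 1.0
        assert all(0.0 <= r <= 5.0 for r in vec.au_range.values())
        # 12 AU ranges + 1 gaze proportion = 13 instrumental variables
        assert len(vec.au_range) + 1 == 13

    def test_too_few_frames_flags_excluded_not_dropped(self, tiny_cohort):
        trial = tiny_cohort.trials[0]
        ann = trial.annotation
        vec = extract_trial_features(
            trial.frames.head(10), ann, QCConfig(min_frames=300)
        )
        assert vec.excluded
        assert "min_frames" in vec.exclusion_reason
        assert vec.n_frames_used == 10

    def test_low_retained_fraction_flags_excluded(self, tiny_cohort):
        # the trial span covers 150 frames but only 60 survived QC: below the 0.5 floor
        trial = tiny_cohort.trials[0]
        kept = trial.frames.head(60)
        vec = extract_trial_features(
            kept, trial.annotation, QCConfig(min_frames=30, min_retained=0.5)
        )
        assert vec.excluded
        assert "min_retained" in vec.exclusion_reason

    def test_identical_seed_gives_identical_features(self):
        spec = CohortSpec(n_subjects=2, n_men=1, n_women=1, trial_seconds=4.0,
                          fps=25.0, seed=11)
        qc = QCConfig(min_frames=20)
        tables = []
        for _ in range(2):
            cohort = generate_cohort(spec, EffectSpec())
            vecs = [
                extract_trial_features(filter_frames(t.frames, qc), t.annotation, qc)
                for t in cohort.trials
            ]
            tables.append(features_table(vecs))
        pd.testing.assert_frame_equal(tables[0], tables[1])

    def test_range_computed_on_retained_frames_only(self):
        # a spike confined to a dropped (low-confidence) frame must not inflate the range
        n = 400
        df = pd.DataFrame(
            {
                "frame": np.arange(n),
                "timestamp": np.arange(n) / 30.0,
                "confidence": 0.95,
                "success": True,
                "gaze_angle_x": 0.0,
                "gaze_angle_y": 0.0,
            }
        )
        for au in DEFAULT_AUS:
            df[au] = 1.0
        df.loc[200, "AU06"] = 4.9
        df.loc[200, "confidence"] = 0.1
        ann = TrialAnnotation("S01", "F", "blank", 1, 0, n)
        qc = QCConfig(min_frames=100)
        vec = extract_trial_features(filter_frames(df, qc), ann, qc)
        assert vec.au_range["AU06"] == pytest.approx(0.0)
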