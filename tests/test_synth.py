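"""Synthetic study generator: determinism, calibration, spectral shape,
workload signatures, drift and schedule validation."""

import numpy as np
import pytest
from scipy import signal as sps

from eegworkload.errors import ValidationError
from eegworkload.features import EpochingConfig, extract_features
from eegworkload.synth import (DEFAULT_CHANNELS, HIGH, LOW, TRANSITION,
                               BandComponent, DriftParams, LabelTrack,
                               SignalModelParams, StudySchedule,
                               generate_session, generate_study,
                               study_session_plan)


def _bg_only(rms=30.0, exponent=1.0):
    return SignalModelParams(background_exponent=exponent,
                             background_rms_uV=rms, band_components=(),
                             blink_rate_hz=0.0)


class TestGenerateSession:
    def test_same_seed_is_bit_identical(self, short_schedule):
        model = SignalModelParams(blink_rate_hz=0.0)
        a, _ = generate_session(model, short_schedule, seed=7)
        b, _ = generate_session(model, short_schedule, seed=7)
        assert np.array_equal(a.samples, b.samples)

    def test_different_seed_differs(self, short_schedule):
        model = SignalModelParams()
        a, _ = generate_session(model, short_schedule, seed=7)
        b, _ = generate_session(model, short_schedule, seed=8)
        assert not np.array_equal(a.samples, b.samples)

    def test_background_rms_calibration(self, short_schedule):
        rec, _ = generate_session(_bg_only(30.0), short_schedule, seed=5)
        rms = np.sqrt(np.mean(rec.samples**2, axis=1))
        assert np.all(np.abs(rms - 30.0) / 30.0 < 0.05)

    def test_shape_and_labels(self, short_schedule):
        rec, labels = generate_session(SignalModelParams(), short_schedule, seed=1)
        assert rec.samples.shape == (21, int(550 * 256))
        assert rec.channels == DEFAULT_CHANNELS
        labels.validate(rec.duration_s)
        assert [iv[2] for iv in labels.intervals] == [
            TRANSITION, HIGH, TRANSITION, LOW, TRANSITION]

    def test_background_spectral_slope(self, short_schedule):
        """Welch log-log slope of the 1/f^k background within +-0.3 of -k."""
        for k in (0.5, 1.0):
            rec, _ = generate_session(_bg_only(exponent=k), short_schedule, seed=3)
            f, P = sps.welch(rec.samples[0], fs=rec.rate_hz, nperseg=4096)
            m = (f >= 1) & (f <= 100)
            slope = np.polyfit(np.log10(f[m]), np.log10(P[m]), 1)[0]
            assert abs(slope + k) < 0.3

    def test_workload_gain_scales_band_power(self, feature_schedule):
        """Alpha gain 0.5 halves the RMS, so high/low band power ratio ~ 0.25."""
        model = SignalModelParams(
            background_rms_uV=0.0, blink_rate_hz=0.0,
            band_components=(BandComponent(9.5, 5.0, 10.0, 0.5),),
            channel_mixing=np.ones((21, 1)),
        )
        rec, labels = generate_session(model, feature_schedule, seed=3)
        fs = extract_features(rec, labels, EpochingConfig())
        col = fs.feature_names.index("O1:7-12Hz")
        ratio = (fs.matrix[fs.labels == HIGH, col].mean()
                 / fs.matrix[fs.labels == LOW, col].mean())
        assert ratio == pytest.approx(0.25, rel=0.15)

    def test_blinks_concentrate_on_eog(self, short_schedule):
        model = SignalModelParams(background_rms_uV=5.0, band_components=(),
                                  blink_rate_hz=0.3, blink_amp_uV=150.0)
        rec, _ = generate_session(model, short_schedule, seed=2)
        eog = rec.channels.index("EOGv")
        occ = rec.channels.index("O1")
        assert np.abs(rec.samples[eog]).max() > 3 * np.abs(rec.samples[occ]).max()

    def test_requires_seed(self, short_schedule):
        with pytest.raises(ValidationError, match="seed"):
            generate_session(SignalModelParams(), short_schedule)


class TestScheduleValidation:
    def test_default_schedule_is_valid(self):
        StudySchedule().validate()

    def test_blocks_must_sum_to_session(self):
        bad = StudySchedule(session_length_s=900.0,
                            block_plan=((HIGH, 300.0), (LOW, 300.0)))
        with pytest.raises(ValidationError, match="blocks_sum_to_session"):
            bad.validate()

    def test_states_need_one_minute_transition(self):
        bad = StudySchedule(
            session_length_s=630.0,
            block_plan=((HIGH, 300.0), (TRANSITION, 30.0), (LOW, 300.0)),
        )
        with pytest.raises(ValidationError, match="transition_separation"):
            bad.validate()

    def test_unknown_state_rejected(self):
        bad = StudySchedule(session_length_s=900.0,
                            block_plan=(("medium", 900.0),))
        with pytest.raises(ValidationError, match="known_state"):
            bad.validate()


class TestModelValidation:
    def test_all_unit_gains_rejected(self):
        model = SignalModelParams(
            band_components=(BandComponent(9.5, 5.0, 10.0, 1.0),))
        with pytest.raises(ValidationError, match="distinguishable"):
            model.validate()

    def test_negative_rms_rejected(self):
        with pytest.raises(ValidationError, match="rms"):
            SignalModelParams(background_rms_uV=-1.0).validate()

    def test_mixing_shape_checked(self):
        model = SignalModelParams(channel_mixing=np.ones((21, 5)))
        with pytest.raises(ValidationError, match="mixing_shape"):
            model.validate(21)


class TestStudy:
    def test_default_plan_has_120_sessions(self):
        plan = study_session_plan(StudySchedule())
        assert len(plan) == 8 * 5 * 3
        assert len(set(plan)) == len(plan)

    def test_generated_study_matches_plan(self, short_schedule):
        sch = StudySchedule(n_subjects=2, days=1, sessions_per_day=2,
                            session_length_s=short_schedule.session_length_s,
                            block_plan=short_schedule.block_plan)
        study = generate_study(SignalModelParams(), sch,
                               DriftParams.none(), seed=0)
        keys = [rec.session_key for rec, _ in study]
        assert keys == [(s, d, i) for s, d, i, _ in study_session_plan(sch)]

    def test_zero_drift_sessions_share_band_power_statistics(self, short_schedule):
        """Stationary studies: per-session mean alpha power agrees closely."""
        sch = StudySchedule(n_subjects=1, days=1, sessions_per_day=3,
                            session_length_s=short_schedule.session_length_s,
                            block_plan=short_schedule.block_plan)
        study = generate_study(SignalModelParams(blink_rate_hz=0.0), sch,
                               DriftParams.none(), seed=4)
        means = []
        for rec, labels in study:
            fs = extract_features(rec, labels, EpochingConfig())
            col = fs.feature_names.index("O1:7-12Hz")
            means.append(fs.matrix[:, col].mean())
        assert np.ptp(means) / np.mean(means) < 0.15

    def test_drift_changes_sessions(self, short_schedule):
        sch = StudySchedule(n_subjects=1, days=1, sessions_per_day=2,
                            session_length_s=short_schedule.session_length_s,
                            block_plan=short_schedule.block_plan)
        drift = DriftParams(session_drift_sd=0.5, day_drift_sd=0.0,
                            within_session_slope=0.0)
        study = generate_study(SignalModelParams(blink_rate_hz=0.0), sch,
                               drift, seed=4)
        rms = [np.sqrt(np.mean(rec.samples**2)) for rec, _ in study]
        assert rms[0] != pytest.approx(rms[1], rel=1e-3)


class TestLabelTrack:
    def test_from_block_plan_covers_session(self):
        track = LabelTrack.from_block_plan(((HIGH, 10.0), (LOW, 5.0)))
        assert track.intervals == ((0.0, 10.0, HIGH), (10.0, 15.0, LOW))
        track.validate(15.0)

    def test_overlap_names_pair(self):
        track = LabelTrack(((0.0, 10.0, HIGH), (5.0, 15.0, LOW)))
        with pytest.raises(ValidationError, match="0 and 1"):
            track.validate()
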