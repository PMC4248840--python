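"""Evaluation protocols, chance resampling and the binomial machinery."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from eegworkload.ann import NetConfig, accuracy, predict
from eegworkload.errors import ValidationError
from eegworkload.features import EpochingConfig, extract_features
from eegworkload.protocols import (ProtocolConfig, _session_pairs,
                                   binomial_all_success_prob, chance_resample,
                                   compare_noise_runs, cross_session_protocol,
                                   curve_from_windows, default_test_structure,
                                   exact_binomial_ci_lower, loocv_protocol,
                                   pooled_accuracy, same_session_eval,
                                   session_training_split,
                                   train_net_from_features)
from eegworkload.synth import (HIGH, LOW, SignalModelParams, StudySchedule,
                               generate_session)

FAST_NET = NetConfig(n_restarts=2, seed=0)


class TestSameSession:
    def test_training_span_is_125_seconds(self, strong_features):
        """The 20 training epochs of each class cover exactly 125 s."""
        train_idx, _ = session_training_split(strong_features)
        for c in (HIGH, LOW):
            starts = strong_features.epoch_start_s[
                train_idx[strong_features.labels[train_idx] == c]]
            assert len(starts) == 20
            assert starts[-1] + 30.0 - starts[0] == pytest.approx(125.0)

    def test_test_windows_span_80_seconds(self, strong_features):
        res = same_session_eval(strong_features, net_config=FAST_NET)
        # 11 consecutive 5 s-stepped epochs of 30 s: 10*5 + 30 = 80 s
        assert res.window_table["n_epochs"].eq(11).all()
        idx = np.flatnonzero(strong_features.labels == HIGH)[20:31]
        starts = strong_features.epoch_start_s[idx]
        assert starts[-1] + 30.0 - starts[0] == pytest.approx(80.0)

    def test_oracle_classifier_gives_constant_unit_curve(self, strong_features):
        res = same_session_eval(strong_features,
                                predict_fn=lambda f: f.labels.copy())
        curve = res.curve
        assert np.all(curve.mean_acc == 1.0)
        assert np.all(curve.dispersion == 0.0)
        assert res.overall_accuracy == 1.0

    def test_gaps_are_positive_and_increasing(self, strong_features):
        res = same_session_eval(strong_features,
                                predict_fn=lambda f: f.labels.copy())
        assert (res.window_table["gap_s"] > 0).all()
        res.curve.validate()

    def test_insufficient_epochs_names_class(self, feature_schedule):
        model = SignalModelParams()
        rec, labels = generate_session(model, feature_schedule, seed=1)
        fs = extract_features(rec, labels)
        cfg = ProtocolConfig(train_epochs_per_class=50)  # 50+11 > 55
        with pytest.raises(ValidationError, match="high"):
            session_training_split(fs, cfg)


class TestCrossSession:
    def test_days_scale_pairs_all_later_sessions(self):
        keys = {("S01", d, s): None for d in range(5) for s in range(3)}
        pairs = _session_pairs(keys, "days")
        assert len(pairs) == 14  # 15 sessions -> 14 later test sessions
        assert all(tr == ("S01", 0, 0) for tr, _ in pairs)

    def test_minutes_and_hours_pair_within_day(self):
        keys = {("S01", d, s): None for d in range(5) for s in range(3)}
        assert [(t[1:], u[1:]) for t, u in _session_pairs(keys, "minutes")] == \
            [((d, 0), (d, 1)) for d in range(5)]
        assert [(t[1:], u[1:]) for t, u in _session_pairs(keys, "hours")] == \
            [((d, 0), (d, 2)) for d in range(5)]

    def test_missing_sessions_reported(self):
        keys = {("S01", 0, 0): None}  # no second session on the day
        with pytest.raises(ValidationError, match="missing_sessions"):
            _session_pairs(keys, "minutes")

    def test_degenerate_reinjection_matches_direct_accuracy(
            self, strong_session, strong_features):
        """Feeding the training session back as a later test session scores
        exactly the directly-computed accuracy of that net on those epochs."""
        rec, labels = strong_session
        rec2 = replace(rec, session_index=1, start_offset_s=1800.0)
        table = cross_session_protocol(
            [(rec, labels), (rec2, labels)], "minutes",
            net_config=FAST_NET)
        net = train_net_from_features(strong_features, FAST_NET)
        direct = accuracy(predict(net, strong_features),
                          strong_features.labels)
        assert table["accuracy"].iloc[0] == pytest.approx(direct)
        assert (table["gap_s"] > 0).all()


class TestLoocv:
    def test_fold_count_and_identical_sessions(self, strong_session):
        """Four identical sessions: four folds, all with equal accuracy."""
        rec, labels = strong_session
        study = [(replace(rec, session_index=i), labels) for i in range(4)]
        res = loocv_protocol(study, net_config=FAST_NET)
        assert len(res.per_fold) == 4
        assert res.per_fold["accuracy"].nunique() == 1
        assert res.overall == pytest.approx(res.per_fold["accuracy"].iloc[0])

    def test_single_session_subject_rejected(self, strong_session):
        rec, labels = strong_session
        with pytest.raises(ValidationError, match="single session"):
            loocv_protocol([(rec, labels)], net_config=FAST_NET)


class TestChanceResample:
    def test_single_epoch_single_run_reproducible(self):
        structure = [("S01", np.array([HIGH], dtype=object))]
        a = chance_resample(structure, 1, seed=3)
        b = chance_resample(structure, 1, seed=3)
        assert a.mean_acc in (0.0, 1.0)
        assert a.mean_acc == b.mean_acc

    def test_one_sided_labels_still_hover_at_half(self):
        structure = [("S01", np.array([HIGH] * 200, dtype=object))]
        res = chance_resample(structure, 2000, seed=1)
        assert res.mean_acc == pytest.approx(0.5, abs=0.01)

    def test_default_structure_shape(self):
        structure = default_test_structure(StudySchedule(), EpochingConfig())
        assert len(structure) == 8 * 14
        assert all(len(labs) == 110 for _, labs in structure)
        assert {np.sum(labs == HIGH) for _, labs in structure} == {55}

    def test_empty_structure_rejected(self):
        with pytest.raises(ValidationError, match="nonempty"):
            chance_resample([], 10, seed=0)

    def test_convergence_rate(self):
        """The run-mean spread shrinks like the binomial standard error."""
        structure = default_test_structure(
            StudySchedule(n_subjects=2, days=2, sessions_per_day=2))
        res = chance_resample(structure, 400, seed=5)
        n_epochs = sum(len(l) for _, l in structure)
        se = 0.5 / np.sqrt(n_epochs)
        assert np.std(res.run_accs) == pytest.approx(se, rel=0.35)


class TestBinomialStats:
    def test_all_success_probability(self):
        assert binomial_all_success_prob(10, 0.5) == pytest.approx(9.766e-4,
                                                                   rel=1e-3)
        assert binomial_all_success_prob(10, 0.5) < 0.001
        assert binomial_all_success_prob(1, 0.5) == 0.5
        assert binomial_all_success_prob(5, 1.0) == 1.0

    def test_all_success_probability_validates(self):
        with pytest.raises(ValidationError):
            binomial_all_success_prob(10, 1.5)
        with pytest.raises(ValidationError):
            binomial_all_success_prob(0, 0.5)

    def test_ci_lower_matches_printed_value(self):
        assert exact_binomial_ci_lower(10, 10, 0.95) == pytest.approx(0.6915,
                                                                      abs=5e-4)
        assert round(exact_binomial_ci_lower(10, 10, 0.95), 2) == 0.69

    def test_ci_lower_zero_successes(self):
        assert exact_binomial_ci_lower(0, 7, 0.95) == 0.0

    @pytest.mark.parametrize("n", range(1, 21))
    def test_ci_lower_closed_form_at_full_success(self, n):
        assert exact_binomial_ci_lower(n, n, 0.95) == pytest.approx(
            0.025 ** (1.0 / n), abs=1e-10)

    def test_ci_lower_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(3, 10), (7, 12), (10, 10)]:
            ref = proportion_confint(k, n, alpha=0.05, method="beta")[0]
            assert exact_binomial_ci_lower(k, n, 0.95) == pytest.approx(
                ref, abs=1e-12)

    def test_ci_lower_validates(self):
        with pytest.raises(ValidationError):
            exact_binomial_ci_lower(5, 3, 0.95)
        with pytest.raises(ValidationError):
            exact_binomial_ci_lower(3, 5, 1.5)


class TestCompareNoiseRuns:
    def test_zero_rms_runs_equal_baseline(self, strong_session,
                                          strong_features):
        rec, labels = strong_session
        net = train_net_from_features(strong_features, FAST_NET)
        comp = compare_noise_runs([(net, rec, labels)], rms_uV=0.0,
                                  n_runs=3, master_seed=1, n_members=3)
        assert np.all(comp.noisy_accs == comp.no_noise_acc)
        assert comp.successes == 0

    def test_success_count_is_consistent(self, strong_session,
                                         strong_features):
        rec, labels = strong_session
        net = train_net_from_features(strong_features, FAST_NET)
        comp = compare_noise_runs([(net, rec, labels)], rms_uV=5.0,
                                  n_runs=3, master_seed=1, n_members=3)
        assert comp.successes == int(
            np.sum(comp.noisy_accs > comp.no_noise_acc))
        assert comp.n_runs == 3


class TestPooling:
    def test_subject_first_averaging(self):
        df = pd.DataFrame({
            "subject": ["A", "A", "A", "B"],
            "accuracy": [1.0, 1.0, 1.0, 0.0],
        })
        # naive mean would be 0.75; subject-first pooling gives 0.5
        assert pooled_accuracy(df) == 0.5

    def test_curve_aggregation_mad(self):
        table = pd.DataFrame({
            "gap_s": [10.0, 10.0, 20.0, 20.0],
            "accuracy": [1.0, 0.5, 0.8, 0.8],
        })
        curve = curve_from_windows(table)
        assert np.allclose(curve.mean_acc, [0.75, 0.8])
        assert np.allclose(curve.dispersion, [0.25, 0.0])
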