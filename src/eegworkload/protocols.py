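"""Evaluation protocols and supporting statistics.

Three regimes quantify classifier performance and its decay over time:

* **same-session**: a network is trained on the first 20 epochs (125 s) of each
  workload block of a session and evaluated on sliding 11-epoch (80 s) test
  windows over the remainder, indexed by the time gap from the training data;
* **cross-session**: the same networks are re-used prospectively on *later*
  sessions — the second session of the day (minutes apart), the last session of
  the day (hours apart), or every session after the very first (days to weeks);
* **leave-one-out**: the time-independent average — per subject, train on all
  sessions but one and test on the held-out one.

Statistical machinery: a chance-level resampler that replaces the classifier
output with a fair coin and analyses it exactly like the real pipeline; the
binomial probability that all of n independent noise runs beat the no-noise
baseline; and the exact (Clopper-Pearson) lower confidence bound for a
proportion, used to bound how often noise injection helps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .ann import NetConfig, WorkloadNet, accuracy, predict, train
from .errors import ValidationError
from .features import EpochingConfig, FeatureSet, epoch_slices, extract_features
from .noise import EnsembleConfig, NoiseConfig, ensemble_predict
from .synth import HIGH, LOW, LabelTrack, Recording, StudySchedule

SCALES = ("minutes", "hours", "days")


@dataclass(frozen=True)
class ProtocolConfig:
    train_epochs_per_class: int = 20
    test_window_epochs: int = 11
    test_window_step_epochs: int = 1
    rms_levels: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0)
    n_chance_runs: int = 1000
    chance_seed: int = 0

    def validate(self) -> None:
        if min(self.train_epochs_per_class, self.test_window_epochs,
               self.test_window_step_epochs) < 1:
            raise ValidationError("positive_counts",
                                  "protocol epoch counts must be >= 1")


@dataclass
class EvalCurve:
    """Accuracy as a function of the time gap from the training data."""

    time_gap_s: np.ndarray
    mean_acc: np.ndarray
    dispersion: np.ndarray  # mean absolute deviation per gap
    grouping: str = ""

    def validate(self) -> None:
        if np.any(np.diff(self.time_gap_s) <= 0):
            raise ValidationError("gaps_increasing", "time gaps must increase")
        if np.any((self.mean_acc < 0) | (self.mean_acc > 1)):
            raise ValidationError("acc_range", "accuracies must lie in [0, 1]")

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.time_gap_s, 100 * self.mean_acc,
                    yerr=100 * self.dispersion, **kwargs)
        ax.set_xlabel("time gap from training data (s)")
        ax.set_ylabel("classification accuracy (%)")
        ax.set_title(self.grouping)
        return ax


def curve_from_windows(window_table: pd.DataFrame, grouping: str = "") -> EvalCurve:
    """Aggregate per-window accuracies into an EvalCurve (mean and mean
    absolute deviation per time gap)."""
    g = window_table.groupby(np.round(window_table["gap_s"], 6))["accuracy"]
    gaps = np.array(sorted(g.groups))
    mean = g.mean().loc[gaps].to_numpy()
    mad = g.apply(lambda a: float(np.mean(np.abs(a - a.mean())))).loc[gaps].to_numpy()
    curve = EvalCurve(gaps, mean, mad, grouping)
    curve.validate()
    return curve


def session_training_split(fs: FeatureSet, protocol: ProtocolConfig = ProtocolConfig()):
    """First ``train_epochs_per_class`` epochs of each class go to training;
    the rest form per-class test streams (index arrays, time-ordered)."""
    protocol.validate()
    train_idx, streams = [], {}
    for c in (HIGH, LOW):
        idx = np.flatnonzero(fs.labels == c)
        need = protocol.train_epochs_per_class + protocol.test_window_epochs
        if len(idx) < need:
            raise ValidationError(
                "sufficient_epochs",
                f"class {c!r} has {len(idx)} epochs; protocol needs >= {need}",
            )
        train_idx.extend(idx[: protocol.train_epochs_per_class])
        streams[c] = idx[protocol.train_epochs_per_class :]
    return np.sort(train_idx), streams


def train_net_from_features(
    fs: FeatureSet,
    net_config: NetConfig = NetConfig(),
    protocol: ProtocolConfig = ProtocolConfig(),
) -> WorkloadNet:
    """Train the per-session network on the session's training segments."""
    train_idx, _ = session_training_split(fs, protocol)
    return train(fs.subset(train_idx), net_config)


def train_session_net(
    recording: Recording,
    labels: LabelTrack,
    epoching: EpochingConfig = EpochingConfig(),
    net_config: NetConfig = NetConfig(),
    protocol: ProtocolConfig = ProtocolConfig(),
):
    """Extract features and train the per-session network."""
    fs = extract_features(recording, labels, epoching)
    train_idx, streams = session_training_split(fs, protocol)
    net = train(fs.subset(train_idx), net_config)
    return net, fs, train_idx, streams


@dataclass
class SameSessionResult:
    net: WorkloadNet
    features: FeatureSet
    window_table: pd.DataFrame
    session_key: tuple

    @property
    def curve(self) -> EvalCurve:
        return curve_from_windows(self.window_table,
                                  grouping=str(self.session_key))

    @property
    def overall_accuracy(self) -> float:
        """Mean of the per-window accuracies (the session's headline figure)."""
        return float(self.window_table["accuracy"].mean())


def same_session_eval(
    fs: FeatureSet,
    epoching: EpochingConfig = EpochingConfig(),
    net_config: NetConfig = NetConfig(),
    protocol: ProtocolConfig = ProtocolConfig(),
    session_key: tuple = (),
    predict_fn=None,
) -> SameSessionResult:
    """Same-session temporal evaluation over an already-extracted FeatureSet.

    ``predict_fn(features) -> labels`` may replace the trained network (used
    for oracle/consistency checks); the network is then not trained.
    """
    train_idx, streams = session_training_split(fs, protocol)
    if predict_fn is None:
        net = train(fs.subset(train_idx), net_config)
        predictor = lambda f: predict(net, f)
    else:
        net, predictor = None, predict_fn

    rows = []
    w = protocol.test_window_epochs
    for c, idx in streams.items():
        # end of the training data of this class's block
        tr_starts = fs.epoch_start_s[np.flatnonzero(fs.labels == c)[
            : protocol.train_epochs_per_class]]
        train_end = tr_starts[-1] + epoching.window_s
        preds = predictor(fs.subset(idx))
        for j in range(0, len(idx) - w + 1, protocol.test_window_step_epochs):
            sel = slice(j, j + w)
            starts = fs.epoch_start_s[idx[sel]]
            center = float(starts.mean() + epoching.window_s / 2)
            rows.append({
                "stream": c,
                "window_index": j,
                "gap_s": center - train_end,
                "n_epochs": w,
                "accuracy": accuracy(preds[sel], fs.labels[idx[sel]]),
            })
    table = pd.DataFrame(rows).sort_values(["gap_s", "stream"]).reset_index(drop=True)
    if (table["gap_s"] <= 0).any():
        raise ValidationError("causal", "test window precedes end of training data")
    return SameSessionResult(net, fs, table, session_key)


def same_session_protocol(
    recording: Recording,
    labels: LabelTrack,
    epoching: EpochingConfig = EpochingConfig(),
    net_config: NetConfig = NetConfig(),
    protocol: ProtocolConfig = ProtocolConfig(),
    predict_fn=None,
) -> SameSessionResult:
    """Same-session temporal evaluation of one labelled recording."""
    fs = extract_features(recording, labels, epoching)
    return same_session_eval(
        fs, epoching, net_config, protocol,
        session_key=recording.session_key, predict_fn=predict_fn,
    )


def _index_study(study):
    by_key = {}
    for rec, labels in study:
        key = rec.session_key
        if key in by_key:
            raise ValidationError("unique_sessions", f"duplicate session {key}")
        by_key[key] = (rec, labels)
    return by_key


def _session_pairs(by_key, scale: str):
    """(train_key, test_key) pairs for a cross-session scale, prospective only."""
    if scale not in SCALES:
        raise ValidationError("known_scale", f"scale must be one of {SCALES}")
    subjects = sorted({k[0] for k in by_key})
    pairs, missing = [], []
    for sid in subjects:
        keys = sorted(k for k in by_key if k[0] == sid)
        days = sorted({k[1] for k in keys})
        if scale in ("minutes", "hours"):
            target = 1 if scale == "minutes" else max(k[2] for k in keys)
            for d in days:
                tr, te = (sid, d, 0), (sid, d, target)
                if tr not in by_key or te not in by_key:
                    missing.append((tr, te))
                elif tr != te:
                    pairs.append((tr, te))
        else:  # days: very first session -> all later sessions
            first = keys[0]
            if first[1] != 0 or first[2] != 0:
                missing.append(((sid, 0, 0), None))
            pairs.extend((first, k) for k in keys[1:])
    if missing:
        raise ValidationError("missing_sessions",
                              f"required sessions missing: {missing}")
    return pairs


def cross_session_from_features(
    feats: dict,
    offsets: dict,
    scale: str,
    net_config: NetConfig = NetConfig(),
    protocol: ProtocolConfig = ProtocolConfig(),
    net_bank: dict | None = None,
) -> pd.DataFrame:
    """Prospective cross-session evaluation at one time scale.

    ``feats`` maps session keys (subject, day, session) to FeatureSets and
    ``offsets`` to session start offsets in study time. Networks are the
    per-session ones trained on the session's training segments (reused from
    ``net_bank`` when given, which is updated in place); every epoch of the
    test session is used as test data.
    """
    pairs = _session_pairs(feats, scale)
    net_bank = net_bank if net_bank is not None else {}
    rows = []
    for tr_key, te_key in pairs:
        if tr_key not in net_bank:
            net_bank[tr_key] = train_net_from_features(
                feats[tr_key], net_config, protocol
            )
        net = net_bank[tr_key]
        gap = offsets[te_key] - offsets[tr_key]
        if gap <= 0:
            raise ValidationError("causal",
                                  f"test session {te_key} not after {tr_key}")
        fs = feats[te_key]
        rows.append({
            "subject": tr_key[0],
            "scale": scale,
            "train_day": tr_key[1], "train_session": tr_key[2],
            "test_day": te_key[1], "test_session": te_key[2],
            "gap_s": gap,
            "n_epochs": fs.n_epochs,
            "accuracy": accuracy(predict(net, fs), fs.labels),
        })
    return pd.DataFrame(rows)


def cross_session_protocol(
    study,
    scale: str,
    epoching: EpochingConfig = EpochingConfig(),
    net_config: NetConfig = NetConfig(),
    protocol: ProtocolConfig = ProtocolConfig(),
    net_bank: dict | None = None,
) -> pd.DataFrame:
    """Cross-session evaluation of a study given as (Recording, LabelTrack)
    pairs; see :func:`cross_session_from_features`."""
    by_key = _index_study(study)
    feats = {k: extract_features(r, l, epoching) for k, (r, l) in by_key.items()}
    offsets = {k: r.start_offset_s for k, (r, _) in by_key.items()}
    return cross_session_from_features(
        feats, offsets, scale, net_config, protocol, net_bank
    )


def scale_accuracy_profile(
    study,
    epoching: EpochingConfig = EpochingConfig(),
    net_config: NetConfig = NetConfig(),
    protocol: ProtocolConfig = ProtocolConfig(),
) -> dict:
    """Pooled accuracy at each temporal scale of a study: same-session plus
    the three cross-session scales, sharing one bank of per-session networks.

    Same-session accuracy is evaluated for the sessions that serve as
    cross-session training sessions (first of each day and the very first).
    """
    by_key = _index_study(study)
    feats = {k: extract_features(r, l, epoching) for k, (r, l) in by_key.items()}
    offsets = {k: r.start_offset_s for k, (r, _) in by_key.items()}
    net_bank: dict = {}
    out = {}
    for scale in SCALES:
        table = cross_session_from_features(
            feats, offsets, scale, net_config, protocol, net_bank)
        out[scale] = pooled_accuracy(table)
    rows = []
    for key in sorted(net_bank):
        res = same_session_eval(
            feats[key], epoching, net_config, protocol, session_key=key,
            predict_fn=lambda f, net=net_bank[key]: predict(net, f),
        )
        rows.append({"subject": key[0], "accuracy": res.overall_accuracy})
    out = {"same": pooled_accuracy(pd.DataFrame(rows)), **out}
    return out


def pooled_accuracy(df: pd.DataFrame) -> float:
    """Pipeline pooling convention: average per-session accuracies within each
    subject first, then across subjects."""
    return float(df.groupby("subject")["accuracy"].mean().mean())


@dataclass
class LoocvResult:
    per_fold: pd.DataFrame
    per_subject: pd.Series
    overall: float


def loocv_from_features(feats: dict, net_config: NetConfig = NetConfig()) -> LoocvResult:
    """Leave-one-session-out cross-validation, per subject, over a dict of
    session-keyed FeatureSets."""
    by_key = feats
    subjects = sorted({k[0] for k in by_key})
    rows = []
    for sid in subjects:
        keys = sorted(k for k in by_key if k[0] == sid)
        if len(keys) < 2:
            raise ValidationError("min_sessions",
                                  f"subject {sid} has a single session")
        for held in keys:
            train_keys = [k for k in keys if k != held]
            fs_train = concat_featuresets([feats[k] for k in train_keys])
            net = train(fs_train, net_config)
            fs_test = feats[held]
            rows.append({
                "subject": sid, "day": held[1], "session": held[2],
                "n_epochs": fs_test.n_epochs,
                "accuracy": accuracy(predict(net, fs_test), fs_test.labels),
            })
    per_fold = pd.DataFrame(rows)
    per_subject = per_fold.groupby("subject")["accuracy"].mean()
    return LoocvResult(per_fold, per_subject, float(per_subject.mean()))


def loocv_protocol(
    study,
    epoching: EpochingConfig = EpochingConfig(),
    net_config: NetConfig = NetConfig(),
) -> LoocvResult:
    """Leave-one-session-out cross-validation of a study given as
    (Recording, LabelTrack) pairs."""
    by_key = _index_study(study)
    feats = {k: extract_features(r, l, epoching) for k, (r, l) in by_key.items()}
    return loocv_from_features(feats, net_config)


def concat_featuresets(sets) -> FeatureSet:
    names = sets[0].feature_names
    for fs in sets:
        if fs.feature_names != names:
            raise ValidationError("matching_features",
                                  "feature sets have different columns")
    return FeatureSet(
        np.vstack([fs.matrix for fs in sets]),
        np.concatenate([fs.epoch_start_s for fs in sets]),
        np.concatenate([fs.labels for fs in sets]),
        names,
    )


# -------------------------------------------------------------- chance level

def session_epoch_labels(block_plan, epoching: EpochingConfig = EpochingConfig()):
    """True epoch labels of a session derived from its block plan alone."""
    labs = []
    for state, dur in block_plan:
        if state in (HIGH, LOW):
            labs.extend([state] * len(epoch_slices(dur, epoching)))
    return np.asarray(labs, dtype=object)


def default_test_structure(
    schedule: StudySchedule = StudySchedule(),
    epoching: EpochingConfig = EpochingConfig(),
    scale: str = "days",
):
    """Cross-session test-epoch structure (per-session true labels, grouped by
    subject) of a study, derived from the schedule without generating signals.

    For the "days" scale these are all sessions after each subject's very
    first one, every epoch used as test data.
    """
    schedule.validate()
    labels = session_epoch_labels(schedule.block_plan, epoching)
    if labels.size == 0:
        raise ValidationError("usable_block", "schedule yields no epochs")
    structure = []
    n_sessions = schedule.days * schedule.sessions_per_day
    test_per_subject = {
        "days": n_sessions - 1,
        "minutes": schedule.days,
        "hours": schedule.days,
    }[scale]
    for i in range(schedule.n_subjects):
        sid = f"S{i + 1:02d}"
        structure.extend((sid, labels) for _ in range(test_per_subject))
    return structure


@dataclass
class ChanceResult:
    mean_acc: float
    max_acc: float
    run_accs: np.ndarray
    n_runs: int


def chance_resample(test_structure, n_runs: int = 1000, seed: int = 0) -> ChanceResult:
    """Replace the classifier with a fair coin and analyse it like the pipeline.

    Per run, every test epoch is marked high or low with probability 0.5
    (regardless of class balance); per-session accuracies are averaged per
    subject and then across subjects, exactly as the real results are pooled.
    Returns the mean and best accuracy over runs (fractions in [0, 1]).
    """
    if n_runs < 1:
        raise ValidationError("n_runs", "n_runs must be >= 1")
    if not test_structure:
        raise ValidationError("nonempty", "empty test structure")
    subjects, is_high, bounds = [], [], [0]
    for sid, labs in test_structure:
        labs = np.asarray(labs, dtype=object)
        if labs.size == 0:
            raise ValidationError("nonempty", f"session of subject {sid} has no epochs")
        subjects.append(sid)
        is_high.append(labs == HIGH)
        bounds.append(bounds[-1] + labs.size)
    truth = np.concatenate(is_high)
    starts = np.asarray(bounds[:-1])
    lengths = np.diff(bounds)

    rng = np.random.default_rng(seed)
    sess_acc = np.empty((n_runs, len(subjects)))
    draws = rng.random((n_runs, truth.size)) < 0.5
    correct = draws == truth[None, :]
    sums = np.add.reduceat(correct, starts, axis=1)
    sess_acc = sums / lengths[None, :]

    subj_ids = np.asarray(subjects)
    run_accs = np.empty(n_runs)
    uniq = np.unique(subj_ids)
    subj_means = np.stack([sess_acc[:, subj_ids == s].mean(axis=1) for s in uniq])
    run_accs = subj_means.mean(axis=0)
    return ChanceResult(
        mean_acc=float(run_accs.mean()),
        max_acc=float(run_accs.max()),
        run_accs=run_accs,
        n_runs=n_runs,
    )


# ----------------------------------------------------- binomial run analysis

def binomial_all_success_prob(n_runs: int, p: float) -> float:
    """P(all n runs succeed) under Binomial(n, p), i.e. p**n."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError("p_range", "p must lie in [0, 1]")
    if n_runs < 1:
        raise ValidationError("n_runs", "n_runs must be >= 1")
    return float(p**n_runs)


def exact_binomial_ci_lower(successes: int, trials: int,
                            confidence: float = 0.95) -> float:
    """Exact (Clopper-Pearson) two-sided lower confidence bound for a binomial
    proportion. For successes == trials == n this equals (alpha/2)**(1/n)."""
    if not (0 < confidence < 1):
        raise ValidationError("confidence_range", "confidence must be in (0, 1)")
    if not (0 <= successes <= trials) or trials < 1:
        raise ValidationError("count_range",
                              f"invalid counts {successes}/{trials}")
    if successes == 0:
        return 0.0
    alpha = 1.0 - confidence
    return float(sstats.beta.ppf(alpha / 2.0, successes, trials - successes + 1))


# --------------------------------------------------- noise-run comparison

@dataclass
class RunComparison:
    """No-noise baseline vs repeated independent noise-ensemble runs."""

    no_noise_acc: float
    noisy_accs: np.ndarray
    rms_uV: float

    @property
    def successes(self) -> int:
        """Runs strictly exceeding the no-noise baseline."""
        return int(np.sum(self.noisy_accs > self.no_noise_acc))

    @property
    def n_runs(self) -> int:
        return len(self.noisy_accs)


def compare_noise_runs(
    cases,
    rms_uV: float,
    n_runs: int = 10,
    master_seed: int = 0,
    epoching: EpochingConfig = EpochingConfig(),
    n_members: int = 10,
) -> RunComparison:
    """Repeat the noise-ensemble classification ``n_runs`` times with
    independent noise and compare each run to the noise-free baseline.

    ``cases``: list of (net, recording, labels) — nets trained noise-free,
    each applied to its paired test session. Accuracies are averaged over
    cases per run.
    """
    if not cases:
        raise ValidationError("nonempty", "no (net, recording, labels) cases")
    base, truths = [], []
    for net, rec, labels in cases:
        fs = extract_features(rec, labels, epoching)
        truths.append(fs.labels)
        base.append(accuracy(predict(net, fs), fs.labels))
    no_noise = float(np.mean(base))

    run_seeds = np.random.SeedSequence(master_seed).generate_state(n_runs) & 0x7FFFFFFF
    noisy = np.empty(n_runs)
    for r in range(n_runs):
        accs = []
        for (net, rec, labels), truth in zip(cases, truths):
            preds = ensemble_predict(
                net, rec, labels, epoching,
                noise=NoiseConfig(rms_uV=rms_uV),
                ensemble=EnsembleConfig(n_members=n_members, seed=int(run_seeds[r])),
            )
            accs.append(accuracy(preds, truth))
        noisy[r] = np.mean(accs)
    return RunComparison(no_noise_acc=no_noise, noisy_accs=noisy, rms_uV=rms_uV)
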