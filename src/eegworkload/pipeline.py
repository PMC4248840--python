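"""End-to-end reproducible runs from a single configuration file.

A run simulates a study, extracts features, trains per-session networks and
executes the requested protocols — same-session, cross-session at all scales,
leave-one-out, chance-level resampling, the noise sweep and the repeated
noise-run comparison — writing every result as a delimited table plus a
machine-readable summary. A single master seed fans out deterministically to
every stochastic component, so identical config + seed gives identical output
tables. Per-session features and networks are cached under ``cache/`` and can
be reloaded with ``resume=True``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ann import NetConfig, accuracy, predict
from .errors import PipelineError, ValidationError
from .features import EpochingConfig, FeatureSet, extract_features
from .io_store import (config_hash, load_net, read_table, save_net,
                       write_run_metadata, write_table)
from .noise import EnsembleConfig, NoiseConfig, ensemble_predict
from .protocols import (ProtocolConfig, SCALES, binomial_all_success_prob,
                        chance_resample, compare_noise_runs,
                        cross_session_from_features, exact_binomial_ci_lower,
                        loocv_from_features, pooled_accuracy,
                        same_session_eval, train_net_from_features)
from .synth import (BandComponent, DriftParams, SignalModelParams,
                    StudySchedule, iter_study_sessions)

log = logging.getLogger("eegworkload")

ALL_STAGES = ("same_session", "cross_session", "loocv", "chance",
              "noise_sweep", "compare_noise")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    schedule: StudySchedule = StudySchedule()
    signal_model: SignalModelParams = SignalModelParams()
    drift: DriftParams = DriftParams()
    epoching: EpochingConfig = EpochingConfig()
    net: NetConfig = NetConfig()
    ensemble: EnsembleConfig = EnsembleConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    protocols: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        self.schedule.validate()
        self.signal_model.validate(len(self.schedule.channel_labels))
        self.drift.validate()
        self.epoching.validate(self.schedule.sampling_rate_hz)
        self.net.validate()
        self.ensemble.validate()
        self.protocol.validate()
        unknown = set(self.protocols) - set(ALL_STAGES)
        if unknown:
            raise ValidationError("known_protocols",
                                  f"unknown protocol stages {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["signal_model"]["channel_mixing"] is not None:
            d["signal_model"]["channel_mixing"] = np.asarray(
                d["signal_model"]["channel_mixing"]).tolist()
        return json.loads(json.dumps(d, default=_plain))


def _plain(obj):
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialise {type(obj)}")


def _build(cls, data: dict, convert=None):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValidationError(
            "known_keys",
            f"unknown keys {sorted(unknown)} for {cls.__name__}; "
            f"allowed: {sorted(fields)}",
        )
    if convert:
        data = {k: convert.get(k, lambda v: v)(v) for k, v in data.items()}
    return cls(**data)


def config_from_dict(raw: dict) -> RunConfig:
    """Build a RunConfig from a plain (YAML-loaded) dict, rejecting unknown keys."""
    raw = dict(raw or {})
    sections = {
        "schedule": lambda d: _build(StudySchedule, d, {
            "block_plan": lambda v: tuple((str(s), float(x)) for s, x in v),
            "channel_labels": tuple,
        }),
        "signal_model": lambda d: _build(SignalModelParams, d, {
            "band_components": lambda v: tuple(
                _build(BandComponent, c) for c in v),
            "channel_mixing": lambda v: None if v is None else np.asarray(v, float),
        }),
        "drift": lambda d: _build(DriftParams, d),
        "epoching": lambda d: _build(EpochingConfig, d, {
            "bands_hz": lambda v: tuple((float(a), float(b)) for a, b in v),
        }),
        "net": lambda d: _build(NetConfig, d, {"hidden_layers": tuple}),
        "ensemble": lambda d: _build(EnsembleConfig, d),
        "protocol": lambda d: _build(ProtocolConfig, d,
                                     {"rms_levels": tuple}),
    }
    kwargs = {}
    for key, builder in sections.items():
        if key in raw:
            kwargs[key] = builder(raw.pop(key))
    if "seed" in raw:
        kwargs["seed"] = int(raw.pop("seed"))
    if "protocols" in raw:
        kwargs["protocols"] = tuple(raw.pop("protocols"))
    if raw:
        raise ValidationError("known_keys",
                              f"unknown top-level config keys {sorted(raw)}")
    config = RunConfig(**kwargs)
    config.validate()
    return config


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def _stage(name: str, fn):
    log.info("stage %s ...", name)
    try:
        return fn()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc


def _session_tag(key) -> str:
    return f"{key[0]}_d{key[1]}_s{key[2]}"


def run_pipeline(config: RunConfig, outdir, resume: bool = False) -> dict:
    """Execute the configured stages; returns the summary dict.

    On failure the run directory keeps an ``INCOMPLETE`` marker naming the
    failed stage.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = outdir / "cache"
    cache.mkdir(exist_ok=True)
    cfg_dict = config.to_dict()
    (outdir / "config_resolved.yaml").write_text(yaml.safe_dump(cfg_dict))
    write_run_metadata(outdir / "run_meta.json", config.seed, cfg_dict)
    meta = {"seed": config.seed, "config_sha256": config_hash(cfg_dict)}
    marker = outdir / "INCOMPLETE"
    marker.write_text("run in progress\n")

    stages = config.protocols
    summary: dict = {}
    try:
        feats, offsets, raw_needed = _stage(
            "simulate_and_extract",
            lambda: _simulate_and_extract(config, cache, resume, stages),
        )
        net_bank = {}

        if "same_session" in stages:
            table = _stage("same_session",
                           lambda: _same_session(config, feats, net_bank,
                                                 cache, resume))
            write_table(table, outdir / "same_session.csv", meta)
            per_session = table.groupby(
                ["subject", "day", "session"])["accuracy"].mean().reset_index()
            summary["same_session_accuracy"] = pooled_accuracy(per_session)

        if "cross_session" in stages:
            def _cross():
                parts = [
                    cross_session_from_features(
                        feats, offsets, scale, config.net, config.protocol,
                        net_bank)
                    for scale in SCALES
                ]
                return pd.concat(parts, ignore_index=True)
            table = _stage("cross_session", _cross)
            write_table(table, outdir / "cross_session.csv", meta)
            summary["cross_session_accuracy"] = {
                scale: pooled_accuracy(table[table["scale"] == scale])
                for scale in SCALES
            }

        if "loocv" in stages:
            res = _stage("loocv",
                         lambda: loocv_from_features(feats, config.net))
            write_table(res.per_fold, outdir / "loocv.csv", meta)
            summary["loocv_accuracy"] = res.overall

        if "chance" in stages:
            def _chance():
                structure = _days_structure(feats)
                return chance_resample(structure,
                                       config.protocol.n_chance_runs,
                                       config.protocol.chance_seed)
            res = _stage("chance", _chance)
            summary["chance"] = {
                "mean_pct": 100 * res.mean_acc,
                "max_pct": 100 * res.max_acc,
                "n_runs": res.n_runs,
            }
            (outdir / "chance.json").write_text(
                json.dumps(summary["chance"], indent=2) + "\n")

        if "noise_sweep" in stages:
            table = _stage(
                "noise_sweep",
                lambda: _noise_sweep(config, feats, net_bank, raw_needed),
            )
            write_table(table, outdir / "noise_sweep.csv", meta)
            summary["noise_sweep_accuracy"] = {
                f"{rms:g}": pooled_accuracy(table[table["rms_uV"] == rms])
                for rms in config.protocol.rms_levels
            }

        if "compare_noise" in stages:
            comp = _stage(
                "compare_noise",
                lambda: _compare_noise(config, feats, net_bank, raw_needed),
            )
            summary["compare_noise"] = comp
            (outdir / "compare_noise.json").write_text(
                json.dumps(comp, indent=2) + "\n")

        (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    except PipelineError as exc:
        marker.write_text(f"failed stage: {exc.stage}\n{exc}\n")
        raise
    marker.unlink()
    return summary


def _simulate_and_extract(config: RunConfig, cache: Path, resume: bool, stages):
    """Generate the study session by session, keeping features (cached as CSV)
    plus the raw recordings needed later by the noise stages."""
    need_raw = bool({"noise_sweep", "compare_noise"} & set(stages))
    feats, offsets, raw = {}, {}, {}
    for rec, labels in iter_study_sessions(
        config.signal_model, config.schedule, config.drift, config.seed
    ):
        key = rec.session_key
        cache_file = cache / f"features_{_session_tag(key)}.csv"
        if resume and cache_file.exists():
            fs = FeatureSet.from_frame(read_table(cache_file))
        else:
            fs = extract_features(rec, labels, config.epoching)
            write_table(fs.to_frame(), cache_file)
        feats[key] = fs
        offsets[key] = rec.start_offset_s
        # minutes-scale test sessions feed the noise ensemble on raw signals
        if need_raw and key[2] == 1:
            raw[key] = (rec, labels)
        log.info("session %s: %d epochs", key, fs.n_epochs)
    return feats, offsets, raw


def _session_net(config, feats, net_bank, cache, resume, key):
    if key in net_bank:
        return net_bank[key]
    net_file = cache / f"net_{_session_tag(key)}.npz"
    if resume and net_file.exists():
        net = load_net(net_file)
    else:
        net = train_net_from_features(feats[key], config.net, config.protocol)
        save_net(net_file, net)
    net_bank[key] = net
    return net


def _same_session(config, feats, net_bank, cache, resume):
    rows = []
    for key in sorted(feats):
        net = _session_net(config, feats, net_bank, cache, resume, key)
        res = same_session_eval(
            feats[key], config.epoching, config.net, config.protocol,
            session_key=key,
            predict_fn=lambda f, net=net: predict(net, f),
        )
        t = res.window_table.copy()
        t.insert(0, "session", key[2])
        t.insert(0, "day", key[1])
        t.insert(0, "subject", key[0])
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


def _days_structure(feats):
    structure = []
    for sid in sorted({k[0] for k in feats}):
        keys = sorted(k for k in feats if k[0] == sid)
        structure.extend((sid, feats[k].labels) for k in keys[1:])
    return structure


def _minutes_cases(config, feats, net_bank, raw):
    """(net, recording, labels) cases: day's first-session net applied to the
    day's second session."""
    cases = []
    for key in sorted(raw):
        tr_key = (key[0], key[1], 0)
        if tr_key not in net_bank:
            net_bank[tr_key] = train_net_from_features(
                feats[tr_key], config.net, config.protocol)
        rec, labels = raw[key]
        cases.append((net_bank[tr_key], rec, labels))
    if not cases:
        raise ValidationError(
            "sessions_for_noise",
            "noise stages need second-of-day sessions (session_index 1)",
        )
    return cases


def _noise_sweep(config, feats, net_bank, raw):
    cases = _minutes_cases(config, feats, net_bank, raw)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(config.protocol.rms_levels)) & 0x7FFFFFFF
    rows = []
    for j, rms in enumerate(config.protocol.rms_levels):
        ens = EnsembleConfig(n_members=config.ensemble.n_members,
                             seed=int(seeds[j]))
        for net, rec, labels in cases:
            fs = extract_features(rec, labels, config.epoching)
            preds = ensemble_predict(net, rec, labels, config.epoching,
                                     NoiseConfig(rms_uV=float(rms)), ens)
            rows.append({
                "subject": rec.subject_id,
                "day": rec.day_index,
                "test_session": rec.session_index,
                "rms_uV": float(rms),
                "n_epochs": fs.n_epochs,
                "accuracy": accuracy(preds, fs.labels),
            })
    return pd.DataFrame(rows)


def _compare_noise(config, feats, net_bank, raw):
    cases = _minutes_cases(config, feats, net_bank, raw)
    levels = [r for r in config.protocol.rms_levels if r > 0]
    rms = float(levels[0]) if levels else 5.0
    comp = compare_noise_runs(
        cases, rms, n_runs=10, master_seed=config.seed,
        epoching=config.epoching, n_members=config.ensemble.n_members,
    )
    return {
        "rms_uV": comp.rms_uV,
        "no_noise_accuracy": comp.no_noise_acc,
        "noisy_accuracies": comp.noisy_accs.tolist(),
        "successes": comp.successes,
        "n_runs": comp.n_runs,
        "p_all_better_if_fair_coin": binomial_all_success_prob(comp.n_runs, 0.5),
        "ci95_lower_if_all_better": exact_binomial_ci_lower(
            comp.successes, comp.n_runs, 0.95)
        if comp.successes == comp.n_runs else None,
    }
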