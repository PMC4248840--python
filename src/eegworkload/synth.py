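"""Synthetic multi-subject EEG workload studies.

The generator emulates the structure of an operator-workload experiment:
21-channel (19 EEG + 2 EOG) scalp recordings at 256 Hz in microvolts, organised
as 15-minute sessions containing labelled 5-minute high- and low-workload
blocks separated by >= 1 min transitions, three sessions per day over five days
per subject.

Signal model per channel:

    x(t) = background + sum_j w_cj * r_j * g_j(t) * m_j * s(t) * b_j(t) + blinks

* background: 1/f^k-shaped Gaussian noise, calibrated to a target RMS;
* b_j: unit-RMS band-limited Gaussian noise (4th-order zero-phase Butterworth
  band-pass around the component's center frequency);
* r_j: the component's baseline RMS in microvolts;
* g_j(t): workload envelope -- the component's ``workload_gain`` inside high
  blocks, 1 inside low blocks, linearly interpolated across transitions (the
  classic workload signature is theta up / alpha down under high load);
* m_j: slow session/day drift multiplier (log-normal random walk per subject);
* s(t): optional within-session linear RMS trend;
* w_cj: per-channel topography weight;
* blinks: optional smooth transients concentrated on EOG/frontal channels.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ValidationError

HIGH = "high"
LOW = "low"
TRANSITION = "transition"
STATES = (HIGH, LOW, TRANSITION)

#: 19 scalp positions of the international 10-20 system plus two EOG channels.
EEG_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "T5", "C3", "Cz",
    "C4", "T4", "T6", "P3", "Pz", "P4", "O1", "O2",
)
DEFAULT_CHANNELS = EEG_1020 + ("EOGv", "EOGh")

_FRONTAL = frozenset({"Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"})
_POSTERIOR = frozenset({"T5", "T6", "P3", "Pz", "P4", "O1", "O2"})
_EOG = frozenset({"EOGv", "EOGh"})

#: Nominal spacing between session starts on one day (s) and between days (s).
SESSION_SPACING_S = 1800.0
DAY_SPACING_S = 86400.0


@dataclass(frozen=True)
class BandComponent:
    """One oscillatory component of the signal model."""

    center_hz: float
    bandwidth_hz: float
    rms_uV: float
    #: multiplicative factor applied to the component RMS in the high state
    workload_gain: float

    @property
    def band_edges(self) -> tuple[float, float]:
        half = self.bandwidth_hz / 2.0
        return (self.center_hz - half, self.center_hz + half)


#: Default workload signature: theta (4-7 Hz) rises, alpha (7-12 Hz) falls
#: under high workload.
DEFAULT_COMPONENTS = (
    BandComponent(center_hz=5.5, bandwidth_hz=3.0, rms_uV=6.0, workload_gain=1.6),
    BandComponent(center_hz=9.5, bandwidth_hz=5.0, rms_uV=10.0, workload_gain=0.7),
)


def default_channel_mixing(channels, components) -> np.ndarray:
    """Crude scalp topography: slow components weighted frontally, alpha-range
    components posteriorly, everything attenuated on the EOG channels."""
    W = np.empty((len(channels), len(components)))
    for j, comp in enumerate(components):
        for i, ch in enumerate(channels):
            if ch in _EOG:
                W[i, j] = 0.2
            elif comp.center_hz < 7.0:
                W[i, j] = 1.0 if ch in _FRONTAL else 0.5
            elif comp.center_hz < 13.0:
                W[i, j] = 1.0 if ch in _POSTERIOR else 0.5
            else:
                W[i, j] = 0.7
    return W


@dataclass(frozen=True)
class SignalModelParams:
    """Parameters of the per-channel synthetic EEG signal model."""

    background_exponent: float = 1.0
    background_rms_uV: float = 31.0
    #: one-pole amplifier high-pass corner applied to the background (Hz);
    #: without it, realisation-specific infra-slow 1/f power dominates the
    #: 0-4 Hz band and sessions stop being exchangeable even with zero drift
    background_highpass_hz: float = 0.5
    band_components: tuple[BandComponent, ...] = DEFAULT_COMPONENTS
    blink_rate_hz: float = 0.05
    blink_amp_uV: float = 75.0
    #: (n_channels, n_components) weights; None -> built per channel labels
    channel_mixing: np.ndarray | None = None

    def mixing_for(self, channels) -> np.ndarray:
        if self.channel_mixing is None:
            return default_channel_mixing(channels, self.band_components)
        return np.asarray(self.channel_mixing, dtype=float)

    def validate(self, n_channels: int | None = None) -> None:
        if self.background_rms_uV < 0:
            raise ValidationError("nonnegative_rms", "background_rms_uV must be >= 0")
        if self.background_exponent < 0:
            raise ValidationError("nonnegative_exponent",
                                  "background_exponent must be >= 0")
        if self.blink_rate_hz < 0 or self.blink_amp_uV < 0:
            raise ValidationError("nonnegative_blink",
                                  "blink rate and amplitude must be >= 0")
        for c in self.band_components:
            if c.rms_uV < 0:
                raise ValidationError("nonnegative_rms",
                                      f"component at {c.center_hz} Hz has rms < 0")
            if c.workload_gain <= 0:
                raise ValidationError("positive_gain",
                                      f"component at {c.center_hz} Hz has gain <= 0")
        if self.band_components and all(
            c.workload_gain == 1.0 for c in self.band_components
        ) and any(c.rms_uV > 0 for c in self.band_components):
            raise ValidationError(
                "distinguishable_classes",
                "all workload gains are 1; high and low states would be "
                "indistinguishable by construction",
            )
        if self.channel_mixing is not None:
            W = np.asarray(self.channel_mixing)
            if W.ndim != 2 or W.shape[1] != len(self.band_components):
                raise ValidationError(
                    "mixing_shape",
                    "channel_mixing must have one column per band component",
                )
            if n_channels is not None and W.shape[0] != n_channels:
                raise ValidationError(
                    "mixing_shape",
                    f"channel_mixing has {W.shape[0]} rows, expected {n_channels}",
                )


@dataclass(frozen=True)
class DriftParams:
    """Temporal nonstationarity of the component amplitudes.

    All-zero drift reproduces a stationary study. ``session_drift_sd`` and
    ``day_drift_sd`` are standard deviations of multiplicative log-normal
    steps of a per-subject random walk on component RMS; ``within_session_slope``
    is the fractional linear change of component RMS over one session.
    """

    session_drift_sd: float = 0.08
    day_drift_sd: float = 0.2
    within_session_slope: float = 0.05

    def validate(self) -> None:
        if min(self.session_drift_sd, self.day_drift_sd) < 0:
            raise ValidationError("nonnegative_drift", "drift sds must be >= 0")

    @classmethod
    def none(cls) -> "DriftParams":
        """A stationary study (all drift fields zero)."""
        return cls(0.0, 0.0, 0.0)


DEFAULT_BLOCK_PLAN = (
    (TRANSITION, 100.0),
    (HIGH, 300.0),
    (TRANSITION, 100.0),
    (LOW, 300.0),
    (TRANSITION, 100.0),
)


@dataclass(frozen=True)
class StudySchedule:
    """Session/block layout of a study.

    Defaults mirror the experiment this package emulates: 8 subjects, 5 days,
    3 sessions per day, 15-minute sessions with 5 minutes in each workload
    state separated by transitions of at least one minute, 256 Hz, 21 channels.
    """

    n_subjects: int = 8
    days: int = 5
    sessions_per_day: int = 3
    session_length_s: float = 900.0
    block_plan: tuple[tuple[str, float], ...] = DEFAULT_BLOCK_PLAN
    sampling_rate_hz: float = 256.0
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS

    @property
    def n_sessions(self) -> int:
        return self.n_subjects * self.days * self.sessions_per_day

    def validate(self) -> None:
        if min(self.n_subjects, self.days, self.sessions_per_day) < 1:
            raise ValidationError("positive_counts",
                                  "subject/day/session counts must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("positive_rate", "sampling_rate_hz must be > 0")
        if not self.channel_labels:
            raise ValidationError("channels_present", "channel_labels is empty")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("unique_channels", "channel labels must be unique")
        total = 0.0
        for state, dur in self.block_plan:
            if state not in STATES:
                raise ValidationError("known_state", f"unknown block state {state!r}")
            if dur <= 0:
                raise ValidationError("positive_duration",
                                      "block durations must be > 0")
            total += dur
        if abs(total - self.session_length_s) > 1e-9:
            raise ValidationError(
                "blocks_sum_to_session",
                f"block durations sum to {total} s, session is "
                f"{self.session_length_s} s",
            )
        # consecutive workload states must be separated by >= 60 s of transition
        prev_state, gap = None, 0.0
        for state, dur in self.block_plan:
            if state == TRANSITION:
                gap += dur
                continue
            if prev_state is not None and state != prev_state and gap < 60.0:
                raise ValidationError(
                    "transition_separation",
                    f"{prev_state}->{state} separated by only {gap} s of "
                    "transition (>= 60 s required)",
                )
            prev_state, gap = state, 0.0


@dataclass(frozen=True)
class Recording:
    """A multi-channel EEG session in microvolts."""

    samples: np.ndarray  # (channels, time), microvolts
    rate_hz: float
    channels: tuple[str, ...]
    subject_id: str = "S01"
    day_index: int = 0
    session_index: int = 0
    #: nominal clock time of session start within the study (s)
    start_offset_s: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "channels", tuple(self.channels))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def session_key(self) -> tuple[str, int, int]:
        return (self.subject_id, self.day_index, self.session_index)

    def validate(self) -> None:
        if self.rate_hz <= 0:
            raise ValidationError("positive_rate", "rate_hz must be > 0")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValidationError(
                "channel_count",
                f"samples has {self.samples.shape[0]} rows for "
                f"{len(self.channels)} channel labels",
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("finite_samples", "samples contain NaN/inf")


@dataclass(frozen=True)
class LabelTrack:
    """Per-session workload annotation as ordered half-open [start_s, end_s)
    intervals covering the session."""

    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self):
        object.__setattr__(
            self,
            "intervals",
            tuple((float(s), float(e), str(st)) for s, e, st in self.intervals),
        )

    @classmethod
    def from_block_plan(cls, block_plan) -> "LabelTrack":
        t, out = 0.0, []
        for state, dur in block_plan:
            out.append((t, t + dur, state))
            t += dur
        return cls(tuple(out))

    @property
    def duration_s(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0

    def validate(self, duration_s: float | None = None) -> None:
        prev_end = None
        for i, (s, e, st) in enumerate(self.intervals):
            if st not in STATES:
                raise ValidationError("known_state", f"unknown state {st!r}")
            if e <= s:
                raise ValidationError("positive_duration",
                                      f"interval {i} has end <= start")
            if prev_end is not None and s < prev_end - 1e-9:
                raise ValidationError(
                    "non_overlapping",
                    f"intervals {i - 1} and {i} overlap "
                    f"([..., {prev_end}) vs [{s}, ...))",
                )
            prev_end = e
        if duration_s is not None and self.intervals:
            if abs(self.duration_s - duration_s) > 1e-6:
                raise ValidationError(
                    "aligned_duration",
                    f"labels cover {self.duration_s} s, recording lasts "
                    f"{duration_s} s",
                )

    def state_blocks(self, states=(HIGH, LOW)):
        """Contiguous blocks restricted to the given states, time-ordered."""
        return [iv for iv in self.intervals if iv[2] in states]


def _unit_rms(x: np.ndarray, axis=-1) -> np.ndarray:
    rms = np.sqrt(np.mean(np.square(x), axis=axis, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _one_over_f_noise(rng, n_channels, n, rate, exponent, highpass_hz=0.0) -> np.ndarray:
    """Gaussian noise with PSD ~ 1/f^exponent above a one-pole high-pass
    corner, unit RMS per channel."""
    white = rng.standard_normal((n_channels, n))
    if exponent == 0 and highpass_hz == 0:
        return _unit_rms(white)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    if highpass_hz > 0:
        shape[1:] *= freqs[1:] / np.sqrt(freqs[1:] ** 2 + highpass_hz**2)
    shaped = np.fft.irfft(spec * shape, n=n, axis=-1)
    return _unit_rms(shaped)


def _component_noise(rng, n, rate, comp: BandComponent) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise for one component."""
    lo, hi = comp.band_edges
    lo = max(lo, 1e-3)
    hi = min(hi, rate / 2 * 0.999)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return _unit_rms(x[None, :])[0]


def _gain_envelope(labels: LabelTrack, gain: float, n: int, rate: float) -> np.ndarray:
    """Per-sample RMS factor: gain in high blocks, 1 in low blocks, linear
    ramps across transitions."""
    env = np.ones(n)
    value = {HIGH: gain, LOW: 1.0}
    ivs = labels.intervals
    for i, (s, e, st) in enumerate(ivs):
        i0 = min(int(round(s * rate)), n)
        i1 = min(int(round(e * rate)), n)
        if i1 <= i0:
            continue
        if st in value:
            env[i0:i1] = value[st]
        else:
            v_prev = value.get(ivs[i - 1][2]) if i > 0 else None
            v_next = value.get(ivs[i + 1][2]) if i + 1 < len(ivs) else None
            v0 = v_prev if v_prev is not None else (v_next if v_next is not None else 1.0)
            v1 = v_next if v_next is not None else v0
            env[i0:i1] = np.linspace(v0, v1, i1 - i0, endpoint=False)
    return env


def _blink_weights(channels) -> np.ndarray:
    # EOG channels carry blink transients at 10x the weight of EEG channels
    return np.array([1.0 if ch in _EOG else 0.1 for ch in channels])


def _add_blinks(rng, samples, rate, model, channels) -> None:
    duration = samples.shape[1] / rate
    n_events = rng.poisson(model.blink_rate_hz * duration)
    if n_events == 0:
        return
    times = np.sort(rng.uniform(0, duration, size=n_events))
    w = _blink_weights(channels)
    half = int(round(0.25 * rate))  # +/- 250 ms support
    t = np.arange(-half, half + 1) / rate
    template = model.blink_amp_uV * np.exp(-0.5 * (t / 0.08) ** 2)
    n = samples.shape[1]
    for t0 in times:
        c = int(round(t0 * rate))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        samples[:, lo:hi] += np.outer(w, template[lo - (c - half): hi - (c - half)])


def generate_session(
    model: SignalModelParams,
    schedule: StudySchedule,
    drift_state: np.ndarray | None = None,
    seed=None,
    *,
    subject_id: str = "S01",
    day_index: int = 0,
    session_index: int = 0,
    start_offset_s: float = 0.0,
    within_session_slope: float = 0.0,
) -> tuple[Recording, LabelTrack]:
    """Generate one labelled session.

    ``drift_state`` holds one RMS multiplier per band component (defaults to
    ones). Identical inputs and seed give bit-identical output.
    """
    schedule.validate()
    channels = schedule.channel_labels
    model.validate(len(channels))
    if seed is None:
        raise ValidationError("seed_required", "generate_session requires a seed")

    rate = schedule.sampling_rate_hz
    n = int(round(schedule.session_length_s * rate))
    rng = np.random.default_rng(seed)
    labels = LabelTrack.from_block_plan(schedule.block_plan)

    samples = np.zeros((len(channels), n))
    if model.background_rms_uV > 0:
        samples += model.background_rms_uV * _one_over_f_noise(
            rng, len(channels), n, rate, model.background_exponent,
            model.background_highpass_hz,
        )

    comps = model.band_components
    if comps:
        mix = model.mixing_for(channels)
        if drift_state is None:
            drift_state = np.ones(len(comps))
        drift_state = np.asarray(drift_state, dtype=float)
        if drift_state.shape != (len(comps),):
            raise ValidationError(
                "drift_state_shape",
                "drift_state needs one multiplier per band component",
            )
        slope = 1.0 + within_session_slope * (np.arange(n) / n - 0.5)
        for j, comp in enumerate(comps):
            if comp.rms_uV == 0:
                # keep the rng stream aligned regardless of amplitude
                rng.standard_normal(n)
                continue
            base = _component_noise(rng, n, rate, comp)
            env = _gain_envelope(labels, comp.workload_gain, n, rate)
            sig = comp.rms_uV * drift_state[j] * base * env * slope
            samples += np.outer(mix[:, j], sig)

    if model.blink_rate_hz > 0 and model.blink_amp_uV > 0:
        _add_blinks(rng, samples, rate, model, channels)

    rec = Recording(
        samples=samples,
        rate_hz=rate,
        channels=channels,
        subject_id=subject_id,
        day_index=day_index,
        session_index=session_index,
        start_offset_s=start_offset_s,
    )
    rec.validate()
    return rec, labels


def study_session_plan(schedule: StudySchedule):
    """Session identities (subject_id, day, session, start_offset_s) of a study."""
    plan = []
    for i in range(schedule.n_subjects):
        sid = f"S{i + 1:02d}"
        for d in range(schedule.days):
            for s in range(schedule.sessions_per_day):
                offset = d * DAY_SPACING_S + s * SESSION_SPACING_S
                plan.append((sid, d, s, offset))
    return plan


def iter_study_sessions(
    model: SignalModelParams,
    schedule: StudySchedule,
    drift: DriftParams = DriftParams(),
    seed=0,
):
    """Yield (Recording, LabelTrack) for every session of the study.

    Per-subject seeds are spawned deterministically from the master seed; the
    drift multipliers follow a cumulative log-normal walk per subject across
    sessions and days.
    """
    schedule.validate()
    model.validate(len(schedule.channel_labels))
    drift.validate()
    n_comp = len(model.band_components)
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    subj_seqs = master.spawn(schedule.n_subjects)
    for i in range(schedule.n_subjects):
        sid = f"S{i + 1:02d}"
        children = subj_seqs[i].spawn(schedule.days * schedule.sessions_per_day + 1)
        walk_rng = np.random.default_rng(children[0])
        mult = np.ones(n_comp)
        k = 1
        for d in range(schedule.days):
            if d > 0:
                mult = mult * np.exp(walk_rng.normal(0.0, drift.day_drift_sd, n_comp))
            for s in range(schedule.sessions_per_day):
                if s > 0:
                    mult = mult * np.exp(
                        walk_rng.normal(0.0, drift.session_drift_sd, n_comp)
                    )
                yield generate_session(
                    model,
                    schedule,
                    drift_state=mult.copy(),
                    seed=children[k],
                    subject_id=sid,
                    day_index=d,
                    session_index=s,
                    start_offset_s=d * DAY_SPACING_S + s * SESSION_SPACING_S,
                    within_session_slope=drift.within_session_slope,
                )
                k += 1


def generate_study(model, schedule, drift: DriftParams = DriftParams(), seed=0):
    """Materialise the full study as a list (see :func:`iter_study_sessions`)."""
    return list(iter_study_sessions(model, schedule, drift, seed))


def subject_seed(master_seed: int, subject_id: str) -> int:
    """Stable small integer seed derived from a master seed and a subject id."""
    return (master_seed * 100003 + zlib.crc32(subject_id.encode())) % (2**31)
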