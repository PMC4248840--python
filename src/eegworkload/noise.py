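"""Test-time noise injection and the parallel-network majority-vote ensemble.

Calibrated white Gaussian noise (stated as an RMS amplitude in microvolts,
bandwidth equal to the Nyquist frequency of the recording) is added
independently to every channel of a recording *at prediction time only* —
"testing with noise", the stochastic-resonance probe — and the classification
is repeated across an array of networks fed with independent noise
realisations, the per-epoch class decided by majority vote (ties go to the
high-workload state). A correlation study quantifies how similar a
noise-corrupted trace remains to the clean one as a function of the section
length used to compute the correlation coefficient.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ann import CLASSES, WorkloadNet, predict
from .errors import ValidationError
from .features import EpochingConfig, extract_features
from .synth import LabelTrack, Recording


@dataclass(frozen=True)
class NoiseConfig:
    """Additive white Gaussian noise at a target RMS amplitude (microvolts)."""

    rms_uV: float = 0.0
    #: white noise at the recording's sampling rate spans [0, Nyquist];
    #: None means "Nyquist of the recording it is applied to"
    bandwidth_hz: float | None = None
    per_channel_independent: bool = True
    seed: object = None

    def validate(self, rate_hz: float | None = None) -> None:
        if self.rms_uV < 0:
            raise ValidationError("nonnegative_rms", "noise rms_uV must be >= 0")
        if (
            self.bandwidth_hz is not None
            and rate_hz is not None
            and abs(self.bandwidth_hz - rate_hz / 2) > 1e-9
        ):
            raise ValidationError(
                "noise_bandwidth",
                f"noise bandwidth {self.bandwidth_hz} Hz must equal the "
                f"recording Nyquist {rate_hz / 2} Hz",
            )


@dataclass(frozen=True)
class EnsembleConfig:
    """Parallel classification array: n networks fed independent noise."""

    n_members: int = 10
    tie_rule: str = "high"
    seed: int = 0

    def validate(self) -> None:
        if self.n_members < 1:
            raise ValidationError("n_members", "n_members must be >= 1")
        if self.tie_rule != "high":
            raise ValidationError("tie_rule", "only tie_rule='high' is supported")


def add_noise(recording: Recording, noise: NoiseConfig) -> Recording:
    """Return a copy of the recording with independent zero-mean Gaussian noise
    of standard deviation ``rms_uV`` added to every channel and sample."""
    noise.validate(recording.rate_hz)
    rng = np.random.default_rng(noise.seed)
    extra = rng.normal(0.0, noise.rms_uV, size=recording.samples.shape)
    return replace(recording, samples=recording.samples + extra)


def majority_vote(member_classes) -> np.ndarray:
    """Per-epoch modal class over ensemble members; exact ties return "high".

    ``member_classes``: sequence of per-member label arrays (members x epochs).
    """
    votes = np.asarray(member_classes, dtype=object)
    if votes.size == 0:
        raise ValidationError("nonempty", "majority_vote of zero members")
    if votes.ndim == 1:
        votes = votes[None, :]
    n_high = np.sum(votes == CLASSES[0], axis=0)
    n_low = np.sum(votes == CLASSES[1], axis=0)
    return np.where(n_high >= n_low, CLASSES[0], CLASSES[1]).astype(object)


def _session_entropy(master_seed: int, recording: Recording) -> list:
    return [
        int(master_seed) & 0x7FFFFFFF,
        zlib.crc32(recording.subject_id.encode()),
        recording.day_index,
        recording.session_index,
    ]


def member_seeds(master_seed: int, recording: Recording, n_members: int):
    """Reproducible independent seeds per ensemble member, bound to the
    session identity so different sessions get different noise."""
    ss = np.random.SeedSequence(_session_entropy(master_seed, recording))
    return ss.spawn(n_members)


def ensemble_predict(
    net: WorkloadNet,
    recording: Recording,
    labels: LabelTrack,
    epoching: EpochingConfig = EpochingConfig(),
    noise: NoiseConfig = NoiseConfig(),
    ensemble: EnsembleConfig = EnsembleConfig(),
    return_votes: bool = False,
):
    """Classify every epoch with the noise ensemble.

    Each member adds an independent noise realisation to the raw recording,
    re-extracts features and applies the (noise-free trained) network; votes
    are combined per epoch by :func:`majority_vote`. Deterministic given
    ``ensemble.seed``.
    """
    ensemble.validate()
    noise.validate(recording.rate_hz)
    seeds = member_seeds(ensemble.seed, recording, ensemble.n_members)
    votes = []
    for m in range(ensemble.n_members):
        noisy = add_noise(recording, replace(noise, seed=seeds[m]))
        fs = extract_features(noisy, labels, epoching)
        votes.append(predict(net, fs))
    votes = np.asarray(votes, dtype=object)
    combined = majority_vote(votes)
    if return_votes:
        return combined, votes
    return combined


def correlation_vs_section_length(
    recording: Recording,
    noise: NoiseConfig,
    section_lengths_s,
    channel: int = 0,
) -> pd.DataFrame:
    """Pearson correlation between a clean channel and its noise-corrupted copy,
    summarised (min, median, max) over consecutive non-overlapping sections of
    each requested length.

    Short sections systematically under-estimate the long-run correlation while
    inflating its spread, which is why the study is run against the section
    length.
    """
    noisy = add_noise(recording, noise)
    clean = recording.samples[channel]
    dirty = noisy.samples[channel]
    rate = recording.rate_hz
    rows = []
    for L in section_lengths_s:
        n = int(round(L * rate))
        if n < 2 or n > clean.size:
            raise ValidationError(
                "section_length",
                f"section of {L} s does not fit the {recording.duration_s} s recording",
            )
        n_sec = clean.size // n
        rs = np.empty(n_sec)
        for k in range(n_sec):
            a = clean[k * n : (k + 1) * n]
            b = dirty[k * n : (k + 1) * n]
            if noise.rms_uV == 0:
                rs[k] = 1.0  # identical traces
            else:
                rs[k] = np.corrcoef(a, b)[0, 1]
        rows.append(
            {
                "section_length_s": float(L),
                "n_sections": n_sec,
                "min": rs.min(),
                "median": float(np.median(rs)),
                "max": rs.max(),
            }
        )
    return pd.DataFrame(rows)


def expected_correlation(signal_rms: float, noise_rms: float) -> float:
    """Closed-form attenuation for independent additive noise:
    r = 1 / sqrt(1 + sigma_n^2 / sigma_s^2)."""
    return 1.0 / np.sqrt(1.0 + (noise_rms / signal_rms) ** 2)
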