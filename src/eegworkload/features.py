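"""Epoching and band-power feature extraction.

A labelled recording is converted into epoch feature vectors: the signal is cut
into 30 s epochs advanced every 5 s *within* each contiguous high/low workload
block (transition segments are discarded and no epoch straddles a block
boundary). Per epoch and channel, the power spectrum is estimated by averaging
the magnitude-squared 1024-point FFTs of consecutive non-overlapping segments
(rectangular window, no detrending) and summed over seven frequency bands:
0-4, 4-7, 7-12, 12-30, 30-42, 42-84 and 84-128 Hz. With 21 channels this gives
the 147-dimensional feature vector the classifier consumes.

Band edges are half-open [low, high); the Nyquist bin is assigned to the last
band so that the bands exactly partition the spectrum (Parseval holds over the
partition). Powers are in microvolt-squared (mean power within the band).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synth import HIGH, LOW, LabelTrack, Recording

DEFAULT_BANDS = ((0, 4), (4, 7), (7, 12), (12, 30), (30, 42), (42, 84), (84, 128))


@dataclass(frozen=True)
class EpochingConfig:
    window_s: float = 30.0
    step_s: float = 5.0
    fft_len: int = 1024
    bands_hz: tuple[tuple[float, float], ...] = DEFAULT_BANDS

    @property
    def n_bands(self) -> int:
        return len(self.bands_hz)

    def validate(self, rate_hz: float | None = None) -> None:
        if self.window_s <= 0:
            raise ValidationError("positive_window", "window_s must be > 0")
        if not (0 < self.step_s <= self.window_s):
            raise ValidationError("step_in_window",
                                  "step_s must satisfy 0 < step_s <= window_s")
        if self.fft_len < 2:
            raise ValidationError("fft_len", "fft_len must be >= 2")
        prev_hi = None
        for lo, hi in self.bands_hz:
            if hi <= lo:
                raise ValidationError("band_order", f"band ({lo}, {hi}) is empty")
            if prev_hi is not None and abs(lo - prev_hi) > 1e-9:
                raise ValidationError(
                    "bands_contiguous",
                    f"bands must be contiguous and non-overlapping; got edge "
                    f"{prev_hi} followed by {lo}",
                )
            prev_hi = hi
        if rate_hz is not None and prev_hi is not None and prev_hi > rate_hz / 2 + 1e-9:
            raise ValidationError(
                "band_below_nyquist",
                f"last band edge {prev_hi} Hz exceeds Nyquist {rate_hz / 2} Hz",
            )


def epoch_slices(duration_s: float, config: EpochingConfig = EpochingConfig()) -> np.ndarray:
    """Epoch start times within a block: 0, step, 2*step, ...

    Count is floor((duration - window) / step) + 1; an empty array if the
    block is shorter than one window.
    """
    config.validate()
    if duration_s < config.window_s - 1e-9:
        return np.array([])
    n = int(np.floor((duration_s - config.window_s) / config.step_s + 1e-9)) + 1
    return np.arange(n) * config.step_s


def band_powers(epoch_samples: np.ndarray, rate_hz: float,
                config: EpochingConfig = EpochingConfig()) -> np.ndarray:
    """Band powers of one epoch, shape (..., channels, bands).

    The epoch is split into consecutive non-overlapping ``fft_len``-sample
    segments (remainder discarded), the one-sided magnitude-squared spectra are
    averaged across segments and summed over bins per band.
    """
    config.validate(rate_hz)
    x = np.asarray(epoch_samples, dtype=float)
    n = x.shape[-1]
    n_seg = n // config.fft_len
    if n_seg < 1:
        raise ValidationError(
            "epoch_length",
            f"epoch of {n} samples is shorter than fft_len={config.fft_len}",
        )
    segs = x[..., : n_seg * config.fft_len].reshape(*x.shape[:-1], n_seg, config.fft_len)
    spec = np.fft.rfft(segs, axis=-1)
    p = (spec.real**2 + spec.imag**2) / config.fft_len**2
    # one-sided spectrum: double everything except DC (and Nyquist when present)
    p[..., 1:] *= 2.0
    if config.fft_len % 2 == 0:
        p[..., -1] /= 2.0
    p = p.mean(axis=-2)  # average over segments
    freqs = np.fft.rfftfreq(config.fft_len, d=1.0 / rate_hz)
    out = np.empty(p.shape[:-1] + (config.n_bands,))
    last = config.n_bands - 1
    for j, (lo, hi) in enumerate(config.bands_hz):
        mask = (freqs >= lo) & (freqs < hi)
        if j == last:
            mask |= freqs == hi  # Nyquist bin to the last band
        out[..., j] = p[..., mask].sum(axis=-1)
    return out


@dataclass
class FeatureSet:
    """Epoch-by-feature matrix with per-epoch start times and labels."""

    matrix: np.ndarray  # (epochs, channels * bands)
    epoch_start_s: np.ndarray
    labels: np.ndarray  # per-epoch state, "high" / "low"
    feature_names: tuple[str, ...]
    block_index: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.epoch_start_s = np.asarray(self.epoch_start_s, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.block_index is not None:
            self.block_index = np.asarray(self.block_index, dtype=int)

    @property
    def n_epochs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset(self, idx) -> "FeatureSet":
        idx = np.asarray(idx)
        return FeatureSet(
            self.matrix[idx],
            self.epoch_start_s[idx],
            self.labels[idx],
            self.feature_names,
            None if self.block_index is None else self.block_index[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.feature_names))
        df.insert(0, "label", self.labels)
        df.insert(0, "epoch_start_s", self.epoch_start_s)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureSet":
        meta = [c for c in ("epoch_start_s", "label", "block_index") if c in df.columns]
        names = tuple(c for c in df.columns if c not in meta)
        return cls(
            df[list(names)].to_numpy(float),
            df["epoch_start_s"].to_numpy(float),
            df["label"].to_numpy(object),
            names,
            df["block_index"].to_numpy(int) if "block_index" in df.columns else None,
        )


def feature_names(channels, bands) -> tuple[str, ...]:
    return tuple(f"{ch}:{lo:g}-{hi:g}Hz" for ch in channels for lo, hi in bands)


def extract_features(
    recording: Recording,
    labels: LabelTrack,
    config: EpochingConfig = EpochingConfig(),
) -> FeatureSet:
    """Epoch a labelled recording into band-power feature vectors.

    Epochs are computed per contiguous high/low block independently; transition
    segments are discarded. Raises if no block is at least one window long.
    """
    recording.validate()
    labels.validate(recording.duration_s)
    config.validate(recording.rate_hz)
    rate = recording.rate_hz
    win = int(round(config.window_s * rate))

    rows, starts, lab, block_ix = [], [], [], []
    for b, (s, e, state) in enumerate(labels.state_blocks()):
        for rel in epoch_slices(e - s, config):
            i0 = int(round((s + rel) * rate))
            rows.append(band_powers(recording.samples[:, i0 : i0 + win], rate, config).ravel())
            starts.append(s + rel)
            lab.append(state)
            block_ix.append(b)
    if not rows:
        raise ValidationError(
            "usable_block",
            f"no high/low block of at least window_s={config.window_s} s found",
        )
    order = np.argsort(starts, kind="stable")
    return FeatureSet(
        np.asarray(rows)[order],
        np.asarray(starts)[order],
        np.asarray(lab, dtype=object)[order],
        feature_names(recording.channels, config.bands_hz),
        np.asarray(block_ix)[order],
    )


@dataclass(frozen=True)
class Normalizer:
    """Per-feature affine z-scoring, fitted on training rows only."""

    mean: np.ndarray
    sd: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def fit_normalizer(features, training_rows=None) -> Normalizer:
    """Fit per-column mean/sd statistics on the given training rows.

    ``features`` may be a FeatureSet or a plain matrix; ``training_rows``
    defaults to all rows. Constant columns are rejected by name.
    """
    names = None
    if isinstance(features, FeatureSet):
        names = features.feature_names
        X = features.matrix
    else:
        X = np.asarray(features, dtype=float)
    if training_rows is not None:
        training_rows = np.asarray(training_rows)
        if training_rows.size == 0:
            raise ValidationError("training_rows_nonempty", "training_rows is empty")
        X = X[training_rows]
    if X.shape[0] == 0:
        raise ValidationError("training_rows_nonempty", "no rows to fit normalizer on")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        which = names[bad[0]] if names else f"column {bad[0]}"
        raise ValidationError(
            "nonconstant_feature",
            f"feature {which} is constant on the training rows ({bad.size} total)",
        )
    return Normalizer(mean, sd, names)


def apply_normalizer(normalizer: Normalizer, features):
    """Apply z-scoring; returns the same type as the input."""
    if isinstance(features, FeatureSet):
        return FeatureSet(
            normalizer.transform(features.matrix),
            features.epoch_start_s,
            features.labels,
            features.feature_names,
            features.block_index,
        )
    return normalizer.transform(features)
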