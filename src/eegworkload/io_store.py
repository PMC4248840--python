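"""Reading and writing recordings, labels, manifests, models and result tables.

All amplitudes are microvolts internally; all times are seconds from session
start. Two interchange formats are supported for recordings:

* **EDF** (European Data Format, continuous 16-bit records, no annotations):
  a minimal writer/reader pair. On read, the per-signal physical dimension is
  honoured — ``uV``/``mV``/``V`` are rescaled into microvolts, anything else is
  rejected with a :class:`~eegworkload.errors.UnitError`.
* an internal compressed array container (NumPy ``.npz``) storing samples and
  session identity losslessly.

Labels travel as plain-text interval tables (start_s, end_s, state), studies
as manifest tables listing one session per row.
"""

from __future__ import annotations

import hashlib
import io
import json
import struct
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, UnitError, ValidationError
from .features import Normalizer
from .ann import NetConfig, WorkloadNet
from .synth import LabelTrack, Recording

_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6}
_EDF_HEADER = 256


# ----------------------------------------------------------------- recordings

def write_recording(path, recording: Recording) -> Path:
    """Write a recording; format chosen by suffix (.edf or .npz)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(path, recording)
    elif path.suffix.lower() == ".npz":
        _write_npz(path, recording)
    else:
        raise ValidationError("known_format",
                              f"unsupported recording suffix {path.suffix!r}")
    return path


def read_recording(path) -> Recording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    if path.suffix.lower() == ".npz":
        return _read_npz(path)
    raise ValidationError("known_format",
                          f"unsupported recording suffix {path.suffix!r}")


def _write_npz(path: Path, rec: Recording) -> None:
    rec.validate()
    np.savez_compressed(
        path,
        format_version=np.array(1),
        samples_uV=rec.samples,
        rate_hz=np.array(rec.rate_hz),
        channels=np.array(rec.channels),
        subject_id=np.array(rec.subject_id),
        day_index=np.array(rec.day_index),
        session_index=np.array(rec.session_index),
        start_offset_s=np.array(rec.start_offset_s),
    )


def _read_npz(path: Path) -> Recording:
    try:
        with np.load(path, allow_pickle=False) as z:
            rec = Recording(
                samples=z["samples_uV"],
                rate_hz=float(z["rate_hz"]),
                channels=tuple(str(c) for c in z["channels"]),
                subject_id=str(z["subject_id"]),
                day_index=int(z["day_index"]),
                session_index=int(z["session_index"]),
                start_offset_s=float(z["start_offset_s"]),
            )
    except (zipfile.BadZipFile, OSError, KeyError, ValueError) as exc:
        raise ParseError(f"cannot read container {path}: {exc}",
                         byte_offset=path.stat().st_size if path.exists() else None)
    rec.validate()
    return rec


def _ascii(value, width: int) -> bytes:
    s = f"{value}"[:width]
    return s.encode("ascii").ljust(width)


def _write_edf(path: Path, rec: Recording) -> None:
    rec.validate()
    rate = rec.rate_hz
    if abs(rate - round(rate)) > 1e-9:
        raise ValidationError("integer_rate",
                              "EDF writer needs an integer sampling rate")
    spr = int(round(rate))  # samples per 1 s data record, per channel
    if rec.n_samples % spr != 0:
        raise ValidationError(
            "whole_second_duration",
            "EDF writer needs a whole number of 1 s data records "
            f"(got {rec.n_samples} samples at {spr} Hz)",
        )
    n_rec = rec.n_samples // spr
    ns = rec.n_channels

    pmin = rec.samples.min(axis=1)
    pmax = rec.samples.max(axis=1)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((rec.samples - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    rec_id = (f"subj={rec.subject_id} day={rec.day_index} "
              f"sess={rec.session_index} offset={rec.start_offset_s:g}")
    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii(rec.subject_id, 80))
        fh.write(_ascii(rec_id, 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(_EDF_HEADER * (ns + 1), 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(n_rec, 8))
        fh.write(_ascii(1, 8))
        fh.write(_ascii(ns, 4))
        for ch in rec.channels:
            fh.write(_ascii(ch, 16))
        for _ in range(ns):
            fh.write(_ascii("synthetic", 80))
        for _ in range(ns):
            fh.write(_ascii("uV", 8))
        for v in pmin:
            fh.write(_ascii(f"{v:.8g}"[:8], 8))
        for v in pmax:
            fh.write(_ascii(f"{v:.8g}"[:8], 8))
        for _ in range(ns):
            fh.write(_ascii(dmin, 8))
        for _ in range(ns):
            fh.write(_ascii(dmax, 8))
        for _ in range(ns):
            fh.write(_ascii("", 80))
        for _ in range(ns):
            fh.write(_ascii(spr, 8))
        for _ in range(ns):
            fh.write(_ascii("", 32))
        # records: channel-major within each 1 s record
        data = digital.reshape(ns, n_rec, spr).transpose(1, 0, 2)
        fh.write(data.tobytes())


def _field(raw: bytes, offset: int, width: int, kind=str):
    chunk = raw[offset : offset + width]
    if len(chunk) < width:
        raise ParseError("EDF header truncated", byte_offset=offset)
    text = chunk.decode("ascii", errors="replace").strip()
    if kind is str:
        return text
    try:
        return kind(text)
    except ValueError:
        raise ParseError(f"malformed EDF header field {text!r}", byte_offset=offset)


def _read_edf(path: Path) -> Recording:
    raw = path.read_bytes()
    if len(raw) < _EDF_HEADER:
        raise ParseError("file shorter than EDF header", byte_offset=len(raw))
    subject = _field(raw, 8, 80)
    rec_id = _field(raw, 88, 80)
    header_bytes = _field(raw, 184, 8, int)
    n_rec = _field(raw, 236, 8, int)
    rec_dur = _field(raw, 244, 8, float)
    ns = _field(raw, 252, 4, int)
    if header_bytes != _EDF_HEADER * (ns + 1):
        raise ParseError(
            f"header size field {header_bytes} inconsistent with {ns} signals",
            byte_offset=184,
        )
    if len(raw) < header_bytes:
        raise ParseError("EDF signal headers truncated", byte_offset=len(raw))

    # signal header layout, width per signal: label 16, transducer 80,
    # phys dim 8, phys min 8, phys max 8, dig min 8, dig max 8,
    # prefilter 80, samples-per-record 8, reserved 32
    off = _EDF_HEADER

    def block(width, kind=str):
        nonlocal off
        vals = [_field(raw, off + i * width, width, kind) for i in range(ns)]
        off += width * ns
        return vals

    labels = block(16)
    _transducer = block(80)
    units = block(8)
    pmin = np.array(block(8, float))
    pmax = np.array(block(8, float))
    dmin = np.array(block(8, int))
    dmax = np.array(block(8, int))
    _prefilter = block(80)
    spr = block(8, int)
    _reserved = block(32)

    factors = []
    for u in units:
        if u not in _UNIT_TO_UV:
            raise UnitError(
                f"unsupported physical dimension {u!r}; expected one of "
                f"{sorted(_UNIT_TO_UV)}"
            )
        factors.append(_UNIT_TO_UV[u])
    if len(set(spr)) != 1:
        raise ParseError("per-channel sampling rates differ", byte_offset=off)
    spr0 = spr[0]
    expected = header_bytes + n_rec * ns * spr0 * 2
    if len(raw) < expected:
        raise ParseError(
            f"data truncated: expected {expected} bytes, file has {len(raw)}",
            byte_offset=len(raw),
        )
    data = np.frombuffer(raw[header_bytes:expected], dtype="<i2")
    data = data.reshape(n_rec, ns, spr0).transpose(1, 0, 2).reshape(ns, -1)
    gain = (pmax - pmin) / (dmax - dmin)
    phys = (data - dmin[:, None]) * gain[:, None] + pmin[:, None]
    phys *= np.asarray(factors)[:, None]

    meta = dict(
        item.split("=", 1) for item in rec_id.split() if "=" in item
    )
    rec = Recording(
        samples=phys,
        rate_hz=spr0 / rec_dur,
        channels=tuple(labels),
        subject_id=meta.get("subj", subject or "S01"),
        day_index=int(meta.get("day", 0)),
        session_index=int(meta.get("sess", 0)),
        start_offset_s=float(meta.get("offset", 0.0)),
    )
    rec.validate()
    return rec


# --------------------------------------------------------------------- labels

def write_labels(path, labels: LabelTrack) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\tstate\n")
        for s, e, st in labels.intervals:
            fh.write(f"{s:g}\t{e:g}\t{st}\n")
    return path


def read_labels(path) -> LabelTrack:
    path = Path(path)
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if header and header.split() != ["start_s", "end_s", "state"]:
            raise ParseError(f"unexpected label header {header!r}", byte_offset=0)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"label line {lineno} has {len(parts)} fields")
            rows.append((float(parts[0]), float(parts[1]), parts[2]))
    track = LabelTrack(tuple(rows))
    track.validate()
    return track


# ------------------------------------------------------------------- manifest

@dataclass(frozen=True)
class ManifestEntry:
    path: str
    subject_id: str
    day_index: int
    session_index: int
    label_path: str


@dataclass
class StudyManifest:
    entries: list
    root: Path

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            key = (e.subject_id, e.day_index, e.session_index)
            if key in seen:
                raise ValidationError("unique_sessions",
                                      f"duplicate manifest entry {key}")
            seen.add(key)


def write_manifest(path, entries) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "path": e.path,
                "subject_id": e.subject_id,
                "day_index": e.day_index,
                "session_index": e.session_index,
                "label_path": e.label_path,
            }
            for e in entries
        ]
    )
    df.to_csv(path, index=False)
    return path


def read_manifest(path) -> StudyManifest:
    path = Path(path)
    df = pd.read_csv(path)
    entries = []
    for row in df.itertuples(index=False):
        e = ManifestEntry(
            str(row.path), str(row.subject_id),
            int(row.day_index), int(row.session_index), str(row.label_path),
        )
        for p in (e.path, e.label_path):
            if not (path.parent / p).exists():
                raise ValidationError("paths_exist",
                                      f"manifest references missing file {p}")
        entries.append(e)
    return StudyManifest(entries, root=path.parent)


def load_study(manifest: StudyManifest):
    """Load every session listed in a manifest as (Recording, LabelTrack)."""
    out = []
    for e in manifest.entries:
        rec = read_recording(manifest.root / e.path)
        labels = read_labels(manifest.root / e.label_path)
        out.append((rec, labels))
    return out


# --------------------------------------------------------------------- models

_NET_FORMAT = "eegworkload-net-v1"


def save_net(path, net: WorkloadNet) -> Path:
    path = Path(path)
    arrays = {"norm_mean": net.normalizer.mean, "norm_sd": net.normalizer.sd}
    for i, (W, b) in enumerate(zip(net.weights, net.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    meta = {
        "format": _NET_FORMAT,
        "n_layers": len(net.weights),
        "classes": list(net.classes),
        "config": {
            "hidden_layers": list(net.config.hidden_layers),
            "max_iters": net.config.max_iters,
            "early_stop_patience": net.config.early_stop_patience,
            "train_fraction": net.config.train_fraction,
            "n_restarts": net.config.n_restarts,
            "seed": net.config.seed,
        },
        "training_meta": {k: (float(v) if isinstance(v, np.floating) else v)
                          for k, v in net.training_meta.items()},
        "feature_names": list(net.normalizer.feature_names or []),
    }
    np.savez_compressed(path, meta_json=np.array(json.dumps(meta)), **arrays)
    return path


def load_net(path) -> WorkloadNet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta_json"]))
        if meta.get("format") != _NET_FORMAT:
            raise ParseError(f"not a {_NET_FORMAT} file: {path}")
        n = meta["n_layers"]
        weights = [z[f"W{i}"] for i in range(n)]
        biases = [z[f"b{i}"] for i in range(n)]
        cfg = meta["config"]
        net = WorkloadNet(
            weights=weights,
            biases=biases,
            normalizer=Normalizer(
                z["norm_mean"], z["norm_sd"],
                tuple(meta["feature_names"]) or None,
            ),
            config=NetConfig(
                hidden_layers=tuple(cfg["hidden_layers"]),
                max_iters=cfg["max_iters"],
                early_stop_patience=cfg["early_stop_patience"],
                train_fraction=cfg["train_fraction"],
                n_restarts=cfg["n_restarts"],
                seed=cfg["seed"],
            ),
            training_meta=meta["training_meta"],
            classes=tuple(meta["classes"]),
        )
    return net


# -------------------------------------------------------------- result tables

def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    """Write a results table as CSV with provenance comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_run_metadata(path, seed, config: dict) -> Path:
    import scipy

    from . import __version__

    path = Path(path)
    payload = {
        "seed": seed,
        "config_sha256": config_hash(config),
        "versions": {
            "eegworkload": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
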