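"""Readers and writers for every external representation.

Audio arrives as RIFF PCM WAV, EEG either as EDF or as a delimited
channels x samples text matrix with a small ``key = value`` sidecar,
continuous ratings as CSV (one column per rater), and results leave as
JSON with a config echo for reproducibility.  A built-in 10-20/10-10
electrode table (unit sphere, head-centred, x toward the right ear,
y toward the nasion, z up) supplies positions when the sidecar has none.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("cacor")

__all__ = [
    "Waveform",
    "EEGRecording",
    "RatingSet",
    "STANDARD_61",
    "standard_positions",
    "read_wav",
    "read_eeg",
    "read_ratings",
    "write_results",
    "read_results",
]

#: 61-channel extended 10-20 montage used throughout (mastoids A1/A2 are
#: excluded from analysis because the spherical head model does not cover
#: them).
STANDARD_61 = (
    "Fp1 Fpz Fp2 AF7 AF3 AFz AF4 AF8 "
    "F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 "
    "T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 "
    "P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO7 PO3 POz PO4 PO8 O1 Oz O2"
).split()

EXCLUDED_CHANNELS = ("A1", "A2")

_POSITION_TABLE: dict[str, np.ndarray] | None = None


def _load_position_table() -> dict[str, np.ndarray]:
    """10-20/10-10 positions projected onto the unit sphere.

    Electrode coordinates come from the standard montage shipped with MNE
    (head frame: x right, y nasion, z up).  A sphere is fitted to all
    scalp electrodes by linear least squares and every position is
    re-expressed relative to its centre and normalised to unit radius.
    """
    global _POSITION_TABLE
    if _POSITION_TABLE is not None:
        return _POSITION_TABLE
    import mne

    with np.errstate(all="ignore"):
        try:
            montage = mne.channels.make_standard_montage("colin27_1005")
        except ValueError:  # older MNE naming
            montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    pts = np.array([pos[name] for name in pos])
    # algebraic sphere fit: |x|^2 = 2 x.c + (R^2 - |c|^2)
    A = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3]
    table = {}
    for name, p in pos.items():
        v = np.asarray(p, float) - centre
        n = np.linalg.norm(v)
        if n > 0:
            table[name.upper()] = v / n
    _POSITION_TABLE = table
    return table


def standard_positions(labels) -> np.ndarray:
    """Unit-sphere positions for the given channel labels.

    Raises ``KeyError`` for a label absent from the built-in table.
    """
    table = _load_position_table()
    out = np.empty((len(labels), 3))
    for i, lab in enumerate(labels):
        key = lab.upper()
        if key not in table:
            raise KeyError(
                f"no built-in electrode position for channel {lab!r}; "
                "supply positions explicitly"
            )
        out[i] = table[key]
    return out


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Waveform:
    """Mono audio: samples in [-1, 1] at ``rate`` Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Waveform is mono: samples must be 1-D")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class EEGRecording:
    """channels x samples EEG matrix (microvolts) plus identity metadata."""

    data: np.ndarray
    rate: float
    channel_labels: list
    positions: np.ndarray | None = None
    subject_id: str = ""
    stimulus_id: str = ""
    presentation_index: int = 1

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_labels = list(self.channel_labels)
        if self.positions is None:
            self.positions = standard_positions(self.channel_labels)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.positions.shape != (len(self.channel_labels), 3):
            raise ValueError("positions must be channels x 3")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.presentation_index < 1:
            raise ValueError("presentation_index must be a positive integer")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class RatingSet:
    """raters x samples matrix of nonnegative joystick deflections."""

    ratings: np.ndarray
    rate: float
    stimulus_id: str = ""
    rater_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.ratings = np.atleast_2d(np.asarray(self.ratings, dtype=float))
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if not self.rater_ids:
            self.rater_ids = [f"rater{i + 1}" for i in range(self.n_raters)]
        if len(self.rater_ids) != self.n_raters:
            raise ValueError("rater_ids length mismatch")

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ratings.shape[1]


# ---------------------------------------------------------------------------
# readers


def read_wav(path) -> Waveform:
    """Read a PCM WAV file; stereo is averaged to mono, samples scaled to [-1, 1]."""
    from scipy.io import wavfile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(path)
    except ValueError as err:
        raise ValueError(f"{path} is not a readable PCM WAV file: {err}") from err
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    if data.ndim == 2:  # average channels to mono
        data = data.mean(axis=1)
    return Waveform(samples=data, rate=float(rate))


def _read_sidecar(path) -> dict:
    meta = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        meta[key.strip()] = val.strip()
    return meta


def _drop_excluded(data, labels, positions):
    keep = [i for i, lab in enumerate(labels) if lab.upper() not in EXCLUDED_CHANNELS]
    dropped = [labels[i] for i in range(len(labels)) if i not in keep]
    if dropped:
        logger.info(
            "dropping channels %s: not covered by the spherical head model",
            dropped,
        )
    labels = [labels[i] for i in keep]
    data = data[keep]
    if positions is not None:
        positions = positions[keep]
    return data, labels, positions


def read_eeg(path, metadata=None, **identity) -> EEGRecording:
    """Read an EDF file or a delimited channels x samples matrix.

    For a plain matrix, ``metadata`` is a sidecar path or dict holding at
    least ``rate`` and ``labels`` (comma-separated).  Orientation is
    enforced: if the axis matching the label count is the second one, the
    matrix is transposed.  Mastoid channels A1/A2 are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        labels = list(raw.ch_names)
        positions = None
    else:
        if metadata is None:
            raise ValueError("a sidecar (path or dict) is required for matrix input")
        meta = metadata if isinstance(metadata, dict) else _read_sidecar(metadata)
        if "rate" not in meta or "labels" not in meta:
            raise ValueError("sidecar must define 'rate' and 'labels'")
        try:
            frame = pd.read_csv(path, header=None, sep=None, engine="python")
        except Exception as err:
            raise ValueError(f"could not parse {path} as a numeric matrix: {err}")
        data = frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(data)):
            raise ValueError(f"{path}: non-numeric or non-finite entries")
        labels = [s.strip() for s in str(meta["labels"]).split(",")]
        n = len(labels)
        if data.shape[0] != n and data.shape[1] == n:
            data = data.T
        if data.shape[0] != n:
            raise ValueError(
                f"matrix shape {data.shape} does not match {n} channel labels"
            )
        positions = None
        if "positions" in meta and meta["positions"]:
            positions = np.array(
                [
                    [float(x) for x in row.split()]
                    for row in str(meta["positions"]).split(";")
                ]
            )
        identity.setdefault("subject_id", meta.get("subject_id", ""))
        identity.setdefault("stimulus_id", meta.get("stimulus_id", ""))
        identity.setdefault(
            "presentation_index", int(meta.get("presentation_index", 1))
        )
        rate = float(meta["rate"])
        data, labels, positions = _drop_excluded(data, labels, positions)
        return EEGRecording(
            data=data, rate=rate, channel_labels=labels, positions=positions, **identity
        )
    data, labels, positions = _drop_excluded(data, labels, positions)
    if metadata:
        meta = metadata if isinstance(metadata, dict) else _read_sidecar(metadata)
        identity.setdefault("subject_id", meta.get("subject_id", ""))
        identity.setdefault("stimulus_id", meta.get("stimulus_id", ""))
        identity.setdefault(
            "presentation_index", int(meta.get("presentation_index", 1))
        )
    return EEGRecording(
        data=data,
        rate=float(raw.info["sfreq"]),
        channel_labels=labels,
        positions=positions,
        **identity,
    )


def read_ratings(path, rate: float = 50.0, stimulus_id: str = "") -> RatingSet:
    """Read a ratings CSV: header row, one column per rater, uniform sampling."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except Exception as err:
        raise ValueError(f"could not parse {path} as CSV: {err}")
    if frame.empty or frame.shape[1] == 0:
        raise ValueError(f"{path}: no rating data")
    values = frame.to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: non-numeric rating cell: {err}")
    return RatingSet(
        ratings=values.T,
        rate=rate,
        stimulus_id=stimulus_id,
        rater_ids=[str(c) for c in frame.columns],
    )


# ---------------------------------------------------------------------------
# result serialization


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "__dataclass__": type(obj).__name__,
            **{k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()},
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist()}
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v  # NaN -> null, kept in place
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results(record, path, config=None, seed=None, version="0.1.0") -> None:
    """Serialize any result record (dataclass, dict, DataFrame) to JSON.

    The envelope echoes config and seed so a run can be reproduced; NaN
    p-values are written as ``null`` rather than dropped.
    """
    if isinstance(record, pd.DataFrame):
        payload = {
            "__dataframe__": True,
            "columns": list(map(str, record.columns)),
            "index": list(map(str, record.index)),
            "values": _jsonable(record.to_numpy().tolist()),
        }
    else:
        payload = _jsonable(record)
    envelope = {
        "version": version,
        "seed": seed,
        "config": _jsonable(config.to_dict()) if config is not None else None,
        "record": payload,
    }
    Path(path).write_text(json.dumps(envelope, indent=1, allow_nan=False))


def _revive(obj, registry):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=float)
        if "__dataclass__" in obj:
            name = obj["__dataclass__"]
            fields = {
                k: _revive(v, registry) for k, v in obj.items() if k != "__dataclass__"
            }
            cls = registry.get(name)
            if cls is None:
                return fields
            # null -> NaN for float fields so round-trips are lossless
            for f in dataclasses.fields(cls):
                if fields.get(f.name) is None and f.type in ("float", float):
                    fields[f.name] = float("nan")
            return cls(**fields)
        return {k: _revive(v, registry) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_revive(v, registry) for v in obj]
    return obj


def read_results(path, registry: dict | None = None):
    """Read a result envelope back; known dataclasses are reconstructed."""
    if registry is None:
        from . import cacor_stats, tension_activity

        registry = {
            "CACorResult": cacor_stats.CACorResult,
            "TimeResolvedCACor": cacor_stats.TimeResolvedCACor,
            "ActivityResult": tension_activity.ActivityResult,
        }
    envelope = json.loads(Path(path).read_text())
    envelope["record"] = _revive(envelope.get("record"), registry)
    return envelope
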