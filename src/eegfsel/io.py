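"""Reading and writing trial sets.

Two on-disk formats are supported:

``interchange``
    A directory holding ``data.npy`` (trials x channels x samples, float64)
    plus a ``sidecar.json`` with sampling rate, channel labels, EOG flags,
    asymmetry pairs, labels, ratings and the label scheme.  Round-trips
    exactly.

``edf``
    European Data Format recordings, read through :mod:`mne`.  An EDF file is
    one continuous recording; an optional JSON sidecar next to it (same stem,
    ``.json``) may supply trial segmentation, labels and montage, and is
    validated against the EDF header.  A minimal 16-bit EDF writer is
    provided so synthetic recordings can be exported for tools that expect
    EDF.

Arrays laid out like the DEAP release (trials x 40 channels x samples with a
four-column valence/arousal/dominance/liking rating matrix) can be ingested
directly with :func:`from_deap_arrays`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .data import (
    DEAP_32_CHANNELS,
    FormatError,
    Montage,
    TrialSet,
)

__all__ = ["read_trials", "write_trials", "from_deap_arrays", "FormatError"]

_SIDECAR_REQUIRED = ("fs", "channel_labels")


def _sidecar_dict(ts: TrialSet, montage: Montage | None) -> dict:
    return {
        "fs": ts.fs,
        "channel_labels": list(ts.channel_labels),
        "eog_labels": list(ts.eog_labels),
        "asymmetry_pairs": [list(p) for p in montage.asymmetry_pairs]
        if montage is not None
        else [list(p) for p in Montage.for_labels(ts.eeg_labels).asymmetry_pairs],
        "labels": None if ts.labels is None else ts.labels.tolist(),
        "ratings": None if ts.ratings is None else ts.ratings.tolist(),
        "label_scheme": ts.label_scheme,
        "n_trials": ts.n_trials,
    }


def write_trials(
    ts: TrialSet,
    path: str | Path,
    format: str = "interchange",
    montage: Montage | None = None,
) -> Path:
    """Write a trial set; returns the path written.

    For ``interchange`` the path is a directory (created if needed); for
    ``edf`` it is a file, and trials are concatenated into one continuous
    recording whose sidecar records the trial boundaries.
    """
    path = Path(path)
    if format == "interchange":
        path.mkdir(parents=True, exist_ok=True)
        np.save(path / "data.npy", ts.trials)
        (path / "sidecar.json").write_text(
            json.dumps(_sidecar_dict(ts, montage), indent=1)
        )
        return path
    if format == "edf":
        _write_edf(ts, path)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(_sidecar_dict(ts, montage), indent=1))
        return path
    raise ValueError(f"unknown format {format!r}")


def read_trials(path: str | Path, format: str = "interchange") -> TrialSet:
    """Read a trial set written by :func:`write_trials` (or an EDF file)."""
    path = Path(path)
    if format == "interchange":
        return _read_interchange(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}")


def _load_sidecar(path: Path) -> dict:
    try:
        meta = json.loads(path.read_text())
    except FileNotFoundError:
        raise FormatError(f"missing sidecar {path}") from None
    for key in _SIDECAR_REQUIRED:
        if key not in meta:
            raise FormatError(f"sidecar {path} missing required field {key!r}")
    return meta


def _trialset_from(meta: dict, trials: np.ndarray) -> TrialSet:
    if len(meta["channel_labels"]) != trials.shape[1]:
        raise FormatError(
            f"channel_labels lists {len(meta['channel_labels'])} channels "
            f"but data has {trials.shape[1]}"
        )
    labels = meta.get("labels")
    ratings = meta.get("ratings")
    return TrialSet(
        trials=trials,
        fs=float(meta["fs"]),
        channel_labels=list(meta["channel_labels"]),
        labels=None if labels is None else np.asarray(labels, dtype=int),
        ratings=None if ratings is None else np.asarray(ratings, dtype=float),
        label_scheme=meta.get("label_scheme", "binary"),
        eog_labels=list(meta.get("eog_labels", [])),
    )


def _read_interchange(path: Path) -> TrialSet:
    data_file = path / "data.npy"
    if not data_file.exists():
        raise FormatError(f"missing data file {data_file}")
    trials = np.load(data_file)
    meta = _load_sidecar(path / "sidecar.json")
    return _trialset_from(meta, trials)


# --- EDF ------------------------------------------------------------------


def _read_edf(path: Path) -> TrialSet:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; the package works in uV
    fs = float(raw.info["sfreq"])
    labels = list(raw.ch_names)
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = _load_sidecar(sidecar_path)
        if len(meta["channel_labels"]) != data.shape[0]:
            raise FormatError(
                f"sidecar channel_labels lists {len(meta['channel_labels'])} "
                f"channels but EDF {path.name} has {data.shape[0]}"
            )
        n_trials = int(meta.get("n_trials", 1))
        if data.shape[1] % n_trials:
            raise FormatError(
                f"EDF length {data.shape[1]} not divisible into {n_trials} trials"
            )
        trials = data.reshape(data.shape[0], n_trials, -1).transpose(1, 0, 2)
        return _trialset_from(meta, trials)
    return TrialSet(
        trials=data[None, :, :], fs=fs, channel_labels=labels, label_scheme="binary"
    )


def _write_edf(ts: TrialSet, path: Path) -> None:
    """Minimal EDF export: 16-bit samples, one data record per trial."""
    data = np.concatenate(list(ts.trials), axis=1)  # channels x (trials*samples)
    n_ch = data.shape[0]
    record_samples = ts.n_samples
    n_records = ts.n_trials
    phys_min = float(np.floor(data.min())) if data.size else -1.0
    phys_max = float(np.ceil(data.max())) if data.size else 1.0
    if phys_max <= phys_min:
        phys_max = phys_min + 1.0
    dig_min, dig_max = -32768, 32767

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),          # patient id
            f("Startdate X X X X", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (1 + n_ch)), 8),
            f("", 44),
            f(str(n_records), 8),
            f(f"{record_samples / ts.fs:g}", 8),
            f(str(n_ch), 4),
        ]
    )
    sig = b"".join(f(l, 16) for l in ts.channel_labels)
    sig += b"".join(f("EEG", 80) for _ in range(n_ch))
    sig += b"".join(f("uV", 8) for _ in range(n_ch))
    sig += b"".join(f(f"{phys_min:g}", 8) for _ in range(n_ch))
    sig += b"".join(f(f"{phys_max:g}", 8) for _ in range(n_ch))
    sig += b"".join(f(str(dig_min), 8) for _ in range(n_ch))
    sig += b"".join(f(str(dig_max), 8) for _ in range(n_ch))
    sig += b"".join(f("", 80) for _ in range(n_ch))
    sig += b"".join(f(str(record_samples), 8) for _ in range(n_ch))
    sig += b"".join(f("", 32) for _ in range(n_ch))

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            block = data[:, r * record_samples : (r + 1) * record_samples]
            digital = np.round((block - phys_min) * scale + dig_min)
            digital = np.clip(digital, dig_min, dig_max).astype("<i2")
            fh.write(digital.tobytes())


# --- DEAP-layout arrays ---------------------------------------------------

_DEAP_PERIPHERAL = (
    "hEOG", "vEOG", "zEMG", "tEMG", "GSR", "Resp", "Pleth", "Temp",
)


def from_deap_arrays(
    data: np.ndarray, ratings: np.ndarray, fs: float = 128.0
) -> TrialSet:
    """Ingest arrays laid out like a DEAP subject file.

    ``data`` is ``trials x channels x samples`` with the first 32 channels
    EEG; ``ratings`` is ``trials x 4`` (valence, arousal, dominance, liking).
    Peripheral channels are dropped; valence/arousal ratings are attached and
    quadrant labels derived by thresholding both scales at 5.
    """
    from .evaluation import LabelRule, assign_labels

    data = np.asarray(data)
    ratings = np.asarray(ratings, dtype=float)
    if data.ndim != 3 or data.shape[1] < 32:
        raise FormatError(
            f"expected trials x >=32 channels x samples, got {data.shape}"
        )
    if ratings.shape != (data.shape[0], 4):
        raise FormatError(
            f"expected ratings shape ({data.shape[0]}, 4), got {ratings.shape}"
        )
    va = ratings[:, :2]  # valence, arousal
    labels = assign_labels(va, LabelRule(scheme="quadrant"))
    return TrialSet(
        trials=np.asarray(data[:, :32, :], dtype=float),
        fs=fs,
        channel_labels=list(DEAP_32_CHANNELS),
        labels=labels,
        ratings=va,
        label_scheme="quadrant",
    )
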