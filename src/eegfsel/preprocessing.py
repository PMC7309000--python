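"""Signal conditioning: notch, band-pass FIR, ocular-artifact regression,
resampling, and feature normalization.

All filters operate channel-wise and never change the channel count, except
EOG regression which drops the EOG reference channels after subtracting their
fitted contribution from every EEG channel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .data import EEGRecording, TrialSet

__all__ = [
    "PreprocConfig",
    "notch_filter",
    "bandpass_fir",
    "remove_eog_regression",
    "resample",
    "normalize_features",
    "preprocess_trials",
    "notch_coefficients",
    "fir_coefficients",
]


@dataclass
class PreprocConfig:
    """Filtering and resampling parameters.

    The default band-pass is a 10th-order minimum-phase FIR from 0.1 to 70 Hz.
    At typical EEG rates a 10-tap filter cannot realize a 0.1 Hz low-edge
    transition, so the achieved response is gentle at the low edge; raise
    ``fir_order`` for a sharper filter.  Use :func:`fir_coefficients` to
    inspect the design actually applied.
    """

    notch_freq: float = 50.0
    bp_low: float = 0.1
    bp_high: float = 70.0
    fir_order: int = 10
    fir_phase: str = "minimum"   # "minimum" or "linear"
    target_fs: float = 128.0
    notch_q: float = 30.0
    # stage toggles
    do_notch: bool = True
    do_bandpass: bool = True
    do_eog: bool = True
    do_resample: bool = True

    def __post_init__(self) -> None:
        if self.fir_order < 2:
            raise ValueError("fir_order must be >= 2")
        if not 0 <= self.bp_low < self.bp_high:
            raise ValueError("need 0 <= bp_low < bp_high")
        if self.fir_phase not in ("minimum", "linear"):
            raise ValueError("fir_phase must be 'minimum' or 'linear'")


def notch_coefficients(notch_freq: float, fs: float, q: float = 30.0):
    """Second-order IIR notch (b, a); exported so its response is testable."""
    if notch_freq >= fs / 2:
        raise ValueError(f"notch frequency {notch_freq} Hz >= Nyquist ({fs / 2} Hz)")
    return signal.iirnotch(notch_freq, q, fs=fs)


def notch_filter(
    rec: EEGRecording, notch_freq: float = 50.0, q: float = 30.0
) -> EEGRecording:
    """Remove power-line interference with a narrow IIR notch (zero-phase)."""
    b, a = notch_coefficients(notch_freq, rec.fs, q)
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return replace(rec, data=out)


def fir_coefficients(cfg: PreprocConfig, fs: float) -> np.ndarray:
    """Band-pass FIR taps for the configured order/phase at rate ``fs``."""
    nyq = fs / 2
    if cfg.bp_high >= nyq:
        raise ValueError(f"bp_high {cfg.bp_high} Hz >= Nyquist ({nyq} Hz)")
    if cfg.bp_low <= 0:
        # degenerate low edge: plain low-pass keeping DC
        cutoff, pass_zero = cfg.bp_high, True
    else:
        cutoff, pass_zero = [cfg.bp_low, cfg.bp_high], False
    if cfg.fir_phase == "minimum":
        # design a linear-phase prototype at twice the order, then convert;
        # minimum_phase halves the length back to fir_order + 1 taps
        n = 2 * cfg.fir_order + 1
        proto = signal.firwin(n, cutoff, pass_zero=pass_zero, fs=fs)
        return signal.minimum_phase(proto, method="homomorphic")
    n = cfg.fir_order + 1
    if not pass_zero and n % 2 == 0:
        n += 1  # band-pass needs odd length for a Type-I design
    return signal.firwin(n, cutoff, pass_zero=pass_zero, fs=fs)


def bandpass_fir(rec: EEGRecording, cfg: PreprocConfig) -> EEGRecording:
    """Apply the configured band-pass FIR (causal, so an impulse reproduces
    the exported taps)."""
    taps = fir_coefficients(cfg, rec.fs)
    out = signal.lfilter(taps, 1.0, rec.data, axis=1)
    return replace(rec, data=out)


def remove_eog_regression(rec: EEGRecording) -> EEGRecording:
    """Subtract the least-squares EOG contribution from every EEG channel.

    Coefficients are estimated on the full recording (per trial when driven
    from :func:`preprocess_trials`).  Residual EEG channels are exactly
    uncorrelated with the EOG channels; the EOG channels themselves are
    dropped from the output.
    """
    if not rec.eog_labels:
        raise ValueError("no channels flagged as EOG; cannot regress")
    upper = {l.upper() for l in rec.eog_labels}
    eog_idx = [i for i, l in enumerate(rec.channel_labels) if l.upper() in upper]
    eeg_idx = [i for i in range(rec.n_channels) if i not in eog_idx]
    eog = rec.data[eog_idx]          # (E, S)
    eeg = rec.data[eeg_idx]          # (C, S)
    # least squares of each EEG channel on the EOG channels; lstsq returns
    # the minimum-norm solution, so an all-zero EOG regressor yields beta=0
    beta, *_ = np.linalg.lstsq(eog.T, eeg.T, rcond=None)  # (E, C)
    cleaned = eeg - beta.T @ eog
    return EEGRecording(
        data=cleaned,
        fs=rec.fs,
        channel_labels=[rec.channel_labels[i] for i in eeg_idx],
        eog_labels=[],
    )


def resample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Polyphase anti-aliased downsampling to ``target_fs``."""
    if target_fs > rec.fs:
        raise ValueError(f"cannot upsample from {rec.fs} to {target_fs} Hz")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    n_out = int(np.floor(rec.n_samples * target_fs / rec.fs))
    out = out[:, :n_out]
    return replace(rec, data=out, fs=target_fs)


def preprocess_trials(ts: TrialSet, cfg: PreprocConfig | None = None) -> TrialSet:
    """Run the enabled conditioning stages trial by trial.

    Order: notch -> band-pass FIR -> EOG regression (per-trial coefficients)
    -> resampling.  EOG channels, if regressed out, are removed from the
    returned trial set.
    """
    cfg = cfg or PreprocConfig()
    out = []
    labels_after: list[str] | None = None
    for i in range(ts.n_trials):
        rec = ts.trial_recording(i)
        if cfg.do_notch and cfg.notch_freq < rec.fs / 2:
            rec = notch_filter(rec, cfg.notch_freq, cfg.notch_q)
        if cfg.do_bandpass:
            rec = bandpass_fir(rec, cfg)
        if cfg.do_eog and rec.eog_labels:
            rec = remove_eog_regression(rec)
        if cfg.do_resample and cfg.target_fs < rec.fs:
            rec = resample(rec, cfg.target_fs)
        out.append(rec.data)
        labels_after = rec.channel_labels
        fs_after = rec.fs
    return TrialSet(
        trials=np.stack(out),
        fs=fs_after,
        channel_labels=labels_after,
        labels=ts.labels,
        ratings=ts.ratings,
        label_scheme=ts.label_scheme,
        eog_labels=[],
    )


def normalize_features(
    values: np.ndarray, stats: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Column-wise z-scoring.

    With ``stats`` (mean, sd) supplied — e.g. statistics fitted on training
    folds — they are applied as-is; otherwise they are computed from
    ``values``.  Zero-variance columns map to 0.  Returns the transformed
    matrix and the statistics used, so the exact transform can be reapplied
    to held-out data.
    """
    values = np.asarray(values, dtype=float)
    if stats is None:
        if values.shape[0] < 2:
            raise ValueError("need >= 2 rows to estimate normalization statistics")
        mean = values.mean(axis=0)
        sd = values.std(axis=0)
    else:
        mean, sd = (np.asarray(s, dtype=float) for s in stats)
        if mean.shape != (values.shape[1],) or sd.shape != (values.shape[1],):
            raise ValueError(
                f"stats of dimension {mean.shape}/{sd.shape} do not match "
                f"{values.shape[1]} feature columns"
            )
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (values - mean) / safe_sd
    z[:, sd == 0] = 0.0
    return z, (mean, sd)
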