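"""Multi-domain EEG feature bank.

Per trial and channel the pipeline computes

* six time-domain statistics (mean, population standard deviation, mean
  absolute first/second differences and their sd-normalized versions),
* band power in theta (4-8 Hz), alpha (8-14 Hz), beta (14-30 Hz) and gamma
  (30-50 Hz) from a Welch spectral estimate,
* per-band differential entropy ``h = 1/2 ln(2*pi*e*sigma^2)`` of the
  band-limited signal (Gaussian closed form, natural log),
* rational asymmetry (RASM): the ratio of differential entropies between the
  seven standard left/right electrode pairs, per band,
* entropy and energy of the detail coefficients of a 5-level db4 discrete
  wavelet transform.

With C EEG channels and P asymmetry pairs the assembled matrix has
``F = 24*C + 4*P`` columns: 796 for a 32-channel montage and 748 for a
30-channel montage with the default seven pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal

from .data import Montage, TrialSet

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "StatFeatures",
    "FeatureConfig",
    "FeatureMatrix",
    "statistical_features",
    "band_power",
    "differential_entropy",
    "rasm_features",
    "wavelet_features",
    "extract_all",
]

#: Sentinel reported when a band variance is zero (differential entropy is
#: minus infinity) or a RASM denominator vanishes.
DE_SENTINEL = -np.inf


@dataclass(frozen=True)
class BandSpec:
    """Half-open frequency band [low, high)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band {self.name}: [{self.low}, {self.high})")


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 14.0),
    BandSpec("beta", 14.0, 30.0),
    BandSpec("gamma", 30.0, 50.0),
)


@dataclass(frozen=True)
class StatFeatures:
    """Six time-domain statistics of one channel."""

    mean: float
    std: float                    # population convention (1/N)
    mean_abs_diff1: float
    norm_mean_abs_diff1: float    # mean_abs_diff1 / std (0 when std == 0)
    mean_abs_diff2: float
    norm_mean_abs_diff2: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.mean,
                self.std,
                self.mean_abs_diff1,
                self.norm_mean_abs_diff1,
                self.mean_abs_diff2,
                self.norm_mean_abs_diff2,
            ]
        )


def statistical_features(x: np.ndarray) -> StatFeatures:
    """Time-domain statistics; the second difference spans two samples
    (x[n+2] - x[n]), so at least three samples are required."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D signal with at least 3 samples")
    mu = float(x.mean())
    sigma = float(np.sqrt(np.mean((x - mu) ** 2)))
    d1 = float(np.mean(np.abs(np.diff(x))))
    d2 = float(np.mean(np.abs(x[2:] - x[:-2])))
    nd1 = d1 / sigma if sigma > 0 else 0.0
    nd2 = d2 / sigma if sigma > 0 else 0.0
    return StatFeatures(mu, sigma, d1, nd1, d2, nd2)


@dataclass
class FeatureConfig:
    """Knobs for the spectral estimators and the wavelet decomposition."""

    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    welch_nperseg: int = 256          # capped at the signal length
    welch_overlap: float = 0.5
    wavelet: str = "db4"
    dwt_levels: int = 5
    de_filter_order: int = 4          # Butterworth order for band isolation


def _welch_psd(x: np.ndarray, fs: float, cfg: FeatureConfig):
    nperseg = min(cfg.welch_nperseg, x.size)
    noverlap = int(nperseg * cfg.welch_overlap)
    return signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap
    )


def band_power(
    x: np.ndarray,
    fs: float,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    cfg: FeatureConfig | None = None,
) -> np.ndarray:
    """Integrated Welch PSD over each half-open band [low, high).

    Rectangular integration over the PSD bins means band powers over a
    partition of [0, fs/2) sum to the total signal power (Parseval).
    """
    cfg = cfg or FeatureConfig(bands=bands)
    for b in bands:
        if b.high >= fs / 2 + 1e-9:
            raise ValueError(f"band {b.name} [{b.low},{b.high}) exceeds Nyquist {fs/2}")
    freqs, psd = _welch_psd(np.asarray(x, dtype=float), fs, cfg)
    df = freqs[1] - freqs[0]
    out = np.empty(len(bands))
    for i, b in enumerate(bands):
        mask = (freqs >= b.low) & (freqs < b.high)
        out[i] = psd[mask].sum() * df
    return out


def _band_filter(x: np.ndarray, fs: float, band: BandSpec, order: int) -> np.ndarray:
    sos = signal.butter(
        order, [band.low, band.high], btype="bandpass", fs=fs, output="sos"
    )
    return signal.sosfiltfilt(sos, x)


def differential_entropy(
    x: np.ndarray,
    fs: float,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    cfg: FeatureConfig | None = None,
) -> np.ndarray:
    """Per-band differential entropy under a Gaussian model.

    The band-limited signal is isolated with a zero-phase Butterworth filter,
    its variance estimated with the 1/N convention, and
    ``h = 1/2 ln(2*pi*e*sigma^2)`` evaluated with the natural logarithm.
    Zero variance yields the ``-inf`` sentinel.
    """
    cfg = cfg or FeatureConfig(bands=bands)
    x = np.asarray(x, dtype=float)
    out = np.empty(len(bands))
    for i, b in enumerate(bands):
        if b.high >= fs / 2 + 1e-9:
            raise ValueError(f"band {b.name} exceeds Nyquist {fs / 2}")
        xb = _band_filter(x, fs, b, cfg.de_filter_order)
        var = float(np.mean((xb - xb.mean()) ** 2))
        out[i] = DE_SENTINEL if var == 0 else 0.5 * np.log(2 * np.pi * np.e * var)
    return out


def rasm_features(
    trial: np.ndarray,
    fs: float,
    montage: Montage,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    cfg: FeatureConfig | None = None,
) -> np.ndarray:
    """Rational asymmetry: h(left) / h(right) per pair and band.

    Returns a ``(n_pairs * n_bands,)`` vector, pair-major.  A zero
    denominator yields the sentinel (the ratio is undefined there).
    """
    cfg = cfg or FeatureConfig(bands=bands)
    de = {}
    out = np.empty(len(montage.asymmetry_pairs) * len(bands))
    k = 0
    for left, right in montage.asymmetry_pairs:
        for label in (left, right):
            if label not in de:
                de[label] = differential_entropy(
                    trial[montage.index(label)], fs, bands, cfg
                )
        for bi in range(len(bands)):
            num, den = de[left][bi], de[right][bi]
            out[k] = num / den if den != 0 and np.isfinite(den) else DE_SENTINEL
            k += 1
    return out


def dwt_level_edges(fs: float, levels: int) -> list[tuple[float, float]]:
    """Frequency ranges covered by detail levels D1..Dlevels at rate ``fs``."""
    return [(fs / 2 ** (j + 1), fs / 2 ** j) for j in range(1, levels + 1)]


def wavelet_features(
    x: np.ndarray,
    wavelet: str = "db4",
    levels: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Entropy and energy of detail coefficients per decomposition level.

    Uses periodized boundary handling so the transform is orthogonal and the
    detail/approximation energies sum exactly to the signal energy.  The
    entropy is the log-energy form ``-sum d^2 ln d^2`` over the unnormalized
    squared coefficients, with ``0 ln 0 := 0``.

    Returns ``(ent, eng)``, each of length ``levels``, ordered D1 (finest,
    highest frequencies) to D-levels.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 ** levels:
        raise ValueError(f"signal of length {x.size} too short for {levels} levels")
    # zero-pad to a multiple of 2**levels: periodized DWT is then orthogonal
    # at every level, so detail/approximation energies sum to the signal energy
    block = 2 ** levels
    if x.size % block:
        x = np.pad(x, (0, block - x.size % block))
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="periodization")
    details = coeffs[:0:-1]  # [D1, D2, ..., Dlevels]
    ent = np.empty(levels)
    eng = np.empty(levels)
    for j, d in enumerate(details):
        d2 = d ** 2
        eng[j] = d2.sum()
        nz = d2 > 0
        ent[j] = -np.sum(d2[nz] * np.log(d2[nz]))
    return ent, eng


# --- full matrix assembly -------------------------------------------------


@dataclass
class FeatureMatrix:
    """Trials x features table with stable, self-describing column names."""

    values: np.ndarray
    column_names: list[str]
    family_slices: dict[str, slice] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x features)")
        if len(self.column_names) != self.values.shape[1]:
            raise ValueError("column_names length must match feature count")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("column names must be unique")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.column_names)

    def to_csv(self, path, montage: Montage | None = None) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = {
            "family_slices": {
                k: [s.start, s.stop] for k, s in self.family_slices.items()
            },
            "asymmetry_pairs": [list(p) for p in montage.asymmetry_pairs]
            if montage
            else None,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        import json
        from pathlib import Path

        import pandas as pd

        path = Path(path)
        df = pd.read_csv(path)
        fam = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            fam = {
                k: slice(a, b) for k, (a, b) in meta.get("family_slices", {}).items()
            }
        return cls(df.to_numpy(), list(df.columns), fam)


def feature_count(n_channels: int, n_pairs: int = 7) -> int:
    """Columns produced by full extraction: 6+4+4+10 per channel, 4 per pair."""
    return 24 * n_channels + 4 * n_pairs


def extract_all(
    ts: TrialSet,
    montage: Montage | None = None,
    cfg: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Assemble the full per-trial feature matrix.

    Column order is family-major, channel-major, band-minor:
    ``[stat | psd | de | rasm | wavelet]`` — fixed and documented so that
    selected-feature masks remain portable across runs.  EOG channels are
    excluded.  Wavelet column names carry the frequency edges implied by the
    actual sampling rate.
    """
    cfg = cfg or FeatureConfig()
    eeg = ts.eeg_labels
    if montage is None:
        montage = Montage.for_labels(eeg)
    ch_idx = {l.upper(): i for i, l in enumerate(ts.channel_labels)}
    eeg_idx = [ch_idx[l.upper()] for l in eeg]
    sub_montage = Montage(eeg, montage.asymmetry_pairs)
    bands = cfg.bands

    stat_names = [
        f"stat:{ch}:{name}"
        for ch in eeg
        for name in ("mean", "std", "mad1", "nmad1", "mad2", "nmad2")
    ]
    psd_names = [f"psd:{ch}:{b.name}" for ch in eeg for b in bands]
    de_names = [f"de:{ch}:{b.name}" for ch in eeg for b in bands]
    rasm_names = [
        f"rasm:{l}-{r}:{b.name}"
        for l, r in sub_montage.asymmetry_pairs
        for b in bands
    ]
    edges = dwt_level_edges(ts.fs, cfg.dwt_levels)
    wav_names = [
        f"wav:{ch}:{kind}{j + 1}[{lo:g}-{hi:g}Hz]"
        for ch in eeg
        for kind in ("ent", "eng")
        for j, (lo, hi) in enumerate(edges)
    ]

    rows = []
    for t in range(ts.n_trials):
        trial = ts.trials[t][eeg_idx]
        stat = np.concatenate(
            [statistical_features(trial[c]).as_array() for c in range(len(eeg))]
        )
        psd = np.concatenate(
            [band_power(trial[c], ts.fs, bands, cfg) for c in range(len(eeg))]
        )
        de = np.concatenate(
            [differential_entropy(trial[c], ts.fs, bands, cfg) for c in range(len(eeg))]
        )
        rasm = rasm_features(trial, ts.fs, sub_montage, bands, cfg)
        wavs = []
        for c in range(len(eeg)):
            ent, eng = wavelet_features(trial[c], cfg.wavelet, cfg.dwt_levels)
            wavs.append(np.concatenate([ent, eng]))
        rows.append(np.concatenate([stat, psd, de, rasm, np.concatenate(wavs)]))

    names = stat_names + psd_names + de_names + rasm_names + wav_names
    n_stat, n_psd, n_de = len(stat_names), len(psd_names), len(de_names)
    n_rasm = len(rasm_names)
    offsets = np.cumsum([0, n_stat, n_psd, n_de, n_rasm, len(wav_names)])
    fam = {
        "stat": slice(int(offsets[0]), int(offsets[1])),
        "psd": slice(int(offsets[1]), int(offsets[2])),
        "de": slice(int(offsets[2]), int(offsets[3])),
        "rasm": slice(int(offsets[3]), int(offsets[4])),
        "wavelet": slice(int(offsets[4]), int(offsets[5])),
    }
    return FeatureMatrix(np.stack(rows), names, fam)
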