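"""Data model for multi-channel EEG trials and a synthetic trial generator.

The central container is :class:`TrialSet` — a ``trials x channels x samples``
tensor with sampling rate, 10-20 channel labels and per-trial emotion labels
(binary valence or the four valence/arousal quadrants).  The synthetic
generator plants class-specific band-power effects on chosen channels in a
1/f background so that every downstream stage (preprocessing, feature
extraction, swarm feature selection, cross-validated evaluation) can be
exercised and validated without access to recorded EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EEGRecording",
    "TrialSet",
    "Montage",
    "BandEffect",
    "SynthSpec",
    "EOGInjection",
    "generate_synthetic_trials",
    "inject_eog",
    "DEFAULT_ASYMMETRY_PAIRS",
    "DEAP_32_CHANNELS",
    "ONLINE_30_CHANNELS",
]

#: The seven left/right electrode pairs used for hemispheric-asymmetry ratios.
DEFAULT_ASYMMETRY_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"),
    ("F7", "F8"),
    ("F3", "F4"),
    ("T7", "T8"),
    ("C3", "C4"),
    ("P7", "P8"),
    ("P3", "P4"),
)

#: 32-channel EEG montage in the channel order of the DEAP recordings.
DEAP_32_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: 30-channel 10-20 layout for an online cap where four electrode sites
#: are reserved for horizontal/vertical EOG.
ONLINE_30_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)


class FormatError(ValueError):
    """Raised when an on-disk trial container is inconsistent."""


def _check_labels(labels: list[str]) -> list[str]:
    if len(set(l.upper() for l in labels)) != len(labels):
        raise ValueError("channel labels must be unique (case-insensitive)")
    return list(labels)


@dataclass
class EEGRecording:
    """A single continuous multi-channel recording.

    Parameters
    ----------
    data
        ``channels x samples`` array in microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        One 10-20 name per row of ``data``.
    eog_labels
        Subset of ``channel_labels`` carrying electro-oculogram reference
        signals (used by regression-based ocular artifact removal).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    eog_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_labels = _check_labels(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        upper = {l.upper() for l in self.channel_labels}
        for l in self.eog_labels:
            if l.upper() not in upper:
                raise ValueError(f"EOG label {l!r} not among channel labels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialSet:
    """Labeled collection of fixed-length multi-channel EEG trials."""

    trials: np.ndarray                # (n_trials, n_channels, n_samples)
    fs: float
    channel_labels: list[str]
    labels: np.ndarray | None = None  # per-trial integer class
    ratings: np.ndarray | None = None  # per-trial (valence, arousal), 1-9
    label_scheme: str = "binary"      # "binary" (+1/-1) or "quadrant" (1..4)
    eog_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3:
            raise ValueError("trials must be 3-D (trials x channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_labels = _check_labels(self.channel_labels)
        if len(self.channel_labels) != self.trials.shape[1]:
            raise ValueError("channel label count does not match trial tensor")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.trials.shape[0],):
                raise ValueError("labels length must equal trial count")
            if self.label_scheme == "binary":
                if not set(np.unique(self.labels)) <= {-1, 1}:
                    raise ValueError("binary labels must be in {+1, -1}")
            elif self.label_scheme == "quadrant":
                if not set(np.unique(self.labels)) <= {1, 2, 3, 4}:
                    raise ValueError("quadrant labels must be in {1,2,3,4}")
            else:
                raise ValueError(f"unknown label scheme {self.label_scheme!r}")
        if self.ratings is not None:
            self.ratings = np.asarray(self.ratings, dtype=float)
            if self.ratings.shape[0] != self.trials.shape[0]:
                raise ValueError("ratings length must equal trial count")
        upper = {l.upper() for l in self.channel_labels}
        for l in self.eog_labels:
            if l.upper() not in upper:
                raise ValueError(f"EOG label {l!r} not among channel labels")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    @property
    def eeg_labels(self) -> list[str]:
        """Channel labels excluding EOG reference channels."""
        eog = {l.upper() for l in self.eog_labels}
        return [l for l in self.channel_labels if l.upper() not in eog]

    def trial_recording(self, i: int) -> EEGRecording:
        """View trial ``i`` as a single recording."""
        return EEGRecording(
            self.trials[i], self.fs, list(self.channel_labels), list(self.eog_labels)
        )


@dataclass
class Montage:
    """Channel layout plus the left/right pairs used for asymmetry features."""

    channel_labels: list[str]
    asymmetry_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_ASYMMETRY_PAIRS)
    )

    def __post_init__(self) -> None:
        self.channel_labels = _check_labels(self.channel_labels)
        upper = {l.upper(): i for i, l in enumerate(self.channel_labels)}
        for left, right in self.asymmetry_pairs:
            if left.upper() not in upper or right.upper() not in upper:
                raise ValueError(
                    f"asymmetry pair {left}-{right} not present in channel labels"
                )

    def index(self, label: str) -> int:
        upper = {l.upper(): i for i, l in enumerate(self.channel_labels)}
        return upper[label.upper()]

    @classmethod
    def for_labels(cls, channel_labels: list[str]) -> "Montage":
        """Build a montage keeping only the default pairs present in ``channel_labels``."""
        upper = {l.upper() for l in channel_labels}
        pairs = [
            (a, b)
            for a, b in DEFAULT_ASYMMETRY_PAIRS
            if a.upper() in upper and b.upper() in upper
        ]
        return cls(list(channel_labels), pairs)


@dataclass(frozen=True)
class BandEffect:
    """Multiplicative band-power factor applied on a channel subset for one class."""

    low: float          # Hz
    high: float         # Hz
    channels: tuple[int, ...]
    factor: float       # power ratio relative to the background

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high:
            raise ValueError("band edges must satisfy 0 <= low < high")
        if self.factor <= 0:
            raise ValueError("band-power factor must be positive")


@dataclass
class SynthSpec:
    """Recipe for class-separable synthetic EEG trials.

    Trials are coloured Gaussian noise with a ``1/f**alpha`` power spectrum
    (``alpha`` defaults to 1, the canonical resting EEG slope).  Per class,
    ``band_effects`` multiply the spectral power inside a frequency band on a
    subset of channels, planting a separable oscillatory signature whose
    empirical band-power ratio between classes equals the configured factor.
    """

    n_trials_per_class: int = 10
    n_channels: int = 32
    fs: float = 128.0
    duration: float = 60.0          # seconds
    alpha: float = 1.0              # 1/f exponent of the background
    amplitude: float = 10.0         # background scale, microvolts
    band_effects: dict[int, tuple[BandEffect, ...]] = field(default_factory=dict)
    label_scheme: str = "binary"
    eog_amplitude: float = 0.0      # if > 0, blink artifacts are mixed in
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.label_scheme not in ("binary", "quadrant"):
            raise ValueError(f"unknown label scheme {self.label_scheme!r}")

    @property
    def classes(self) -> tuple[int, ...]:
        return (1, -1) if self.label_scheme == "binary" else (1, 2, 3, 4)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def channel_labels(self) -> list[str]:
        if self.n_channels == 32:
            return list(DEAP_32_CHANNELS)
        if self.n_channels == 30:
            return list(ONLINE_30_CHANNELS)
        return [f"Ch{i + 1:02d}" for i in range(self.n_channels)]


def _one_over_f_amplitude(freqs: np.ndarray, alpha: float) -> np.ndarray:
    amp = np.zeros_like(freqs)
    nonzero = freqs > 0
    amp[nonzero] = freqs[nonzero] ** (-alpha / 2.0)
    return amp


def _synth_trial(
    rng: np.random.Generator,
    spec: SynthSpec,
    effects: tuple[BandEffect, ...],
) -> np.ndarray:
    """One trial: spectrally shaped Gaussian noise, per-band power scaling."""
    n = spec.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    base = _one_over_f_amplitude(freqs, spec.alpha)
    gains = np.tile(base, (spec.n_channels, 1))
    for eff in effects:
        in_band = (freqs >= eff.low) & (freqs < eff.high)
        for ch in eff.channels:
            gains[ch, in_band] *= np.sqrt(eff.factor)
    # Complex Gaussian spectrum => stationary Gaussian signal with PSD ~ gains**2.
    re = rng.standard_normal((spec.n_channels, freqs.size))
    im = rng.standard_normal((spec.n_channels, freqs.size))
    spectrum = gains * (re + 1j * im) / np.sqrt(2.0)
    x = np.fft.irfft(spectrum, n=n, axis=1)
    # Scale to the requested microvolt magnitude (irfft of unit spectrum is tiny).
    return x * spec.amplitude * np.sqrt(n)


_QUADRANT_BOXES = {
    # class -> ((valence_low, valence_high), (arousal_low, arousal_high))
    1: ((5.0, 9.0), (5.0, 9.0)),  # HAHV
    2: ((1.0, 5.0), (5.0, 9.0)),  # HALV
    3: ((5.0, 9.0), (1.0, 5.0)),  # LAHV
    4: ((1.0, 5.0), (1.0, 5.0)),  # LALV
}


def _synth_ratings(
    rng: np.random.Generator, labels: np.ndarray, scheme: str
) -> np.ndarray:
    ratings = np.empty((labels.size, 2))
    for i, lab in enumerate(labels):
        if scheme == "binary":
            v = rng.uniform(5.0, 9.0) if lab == 1 else rng.uniform(1.0, 5.0)
            a = rng.uniform(1.0, 9.0)
        else:
            (vlo, vhi), (alo, ahi) = _QUADRANT_BOXES[int(lab)]
            v = rng.uniform(vlo, vhi)
            a = rng.uniform(alo, ahi)
        ratings[i] = (v, a)
    return ratings


def generate_synthetic_trials(spec: SynthSpec) -> TrialSet:
    """Generate a balanced, class-separable synthetic :class:`TrialSet`.

    Exactly ``spec.n_trials_per_class`` trials are produced per class, in
    class-block order.  The same spec and seed always yield bitwise-identical
    output.  Ratings are drawn uniformly from the valence/arousal region
    consistent with each trial's class (threshold 5).
    """
    rng = np.random.default_rng(spec.seed)
    classes = spec.classes
    trials = []
    labels = []
    for cls in classes:
        effects = tuple(spec.band_effects.get(cls, ()))
        for _ in range(spec.n_trials_per_class):
            trials.append(_synth_trial(rng, spec, effects))
            labels.append(cls)
    labels = np.asarray(labels, dtype=int)
    ratings = _synth_ratings(rng, labels, spec.label_scheme)
    ts = TrialSet(
        trials=np.stack(trials),
        fs=spec.fs,
        channel_labels=spec.channel_labels(),
        labels=labels,
        ratings=ratings,
        label_scheme=spec.label_scheme,
    )
    if spec.eog_amplitude > 0:
        ts = inject_eog(ts, spec.eog_amplitude, seed=spec.seed + 1).trials
    return ts


@dataclass
class EOGInjection:
    """Result of mixing a synthetic blink source into frontal channels."""

    trials: TrialSet               # contaminated, with an explicit EOG channel
    clean: TrialSet                # the uncontaminated input
    mixing: dict[str, float]       # frontal channel label -> mixing coefficient
    source: np.ndarray             # (n_trials, n_samples) blink source


_FRONTAL_PREFIXES = ("FP", "AF", "F3", "F4", "F7", "F8", "FZ")


def _frontal_channels(labels: list[str]) -> list[int]:
    idx = [
        i
        for i, l in enumerate(labels)
        if l.upper().startswith(_FRONTAL_PREFIXES)
    ]
    return idx if idx else [0]


def _blink_source(
    rng: np.random.Generator, n_samples: int, fs: float, amplitude: float
) -> np.ndarray:
    """Sum of smooth ~300 ms blink pulses at random times; spectrum < 4 Hz."""
    t = np.arange(n_samples) / fs
    duration = n_samples / fs
    n_blinks = max(1, rng.poisson(0.25 * duration))
    centers = rng.uniform(0.2, max(duration - 0.2, 0.3), size=n_blinks)
    width = 0.15  # Gaussian sigma in seconds
    src = np.zeros(n_samples)
    for c in centers:
        src += np.exp(-0.5 * ((t - c) / width) ** 2)
    return amplitude * src


def inject_eog(
    trials: TrialSet, eog_amplitude: float, seed: int = 0
) -> EOGInjection:
    """Mix a blink-like low-frequency source into the frontal channels.

    The source is appended as an explicit ``VEOG`` channel and the per-channel
    mixing coefficients are recorded so tests can verify regression-based
    removal.  ``eog_amplitude = 0`` returns the input unchanged (aside from the
    appended, all-zero EOG channel being omitted).
    """
    if eog_amplitude < 0:
        raise ValueError("eog_amplitude must be >= 0")
    if eog_amplitude == 0:
        return EOGInjection(trials=trials, clean=trials, mixing={}, source=np.zeros((trials.n_trials, trials.n_samples)))
    rng = np.random.default_rng(seed)
    frontal = _frontal_channels(trials.channel_labels)
    coefs = rng.uniform(0.4, 0.9, size=len(frontal))
    data = trials.trials.copy()
    source = np.empty((trials.n_trials, trials.n_samples))
    for i in range(trials.n_trials):
        src = _blink_source(rng, trials.n_samples, trials.fs, eog_amplitude)
        source[i] = src
        for j, ch in enumerate(frontal):
            data[i, ch] += coefs[j] * src
    contaminated = TrialSet(
        trials=np.concatenate([data, source[:, None, :]], axis=1),
        fs=trials.fs,
        channel_labels=list(trials.channel_labels) + ["VEOG"],
        labels=trials.labels,
        ratings=trials.ratings,
        label_scheme=trials.label_scheme,
        eog_labels=list(trials.eog_labels) + ["VEOG"],
    )
    mixing = {trials.channel_labels[ch]: float(c) for ch, c in zip(frontal, coefs)}
    return EOGInjection(
        trials=contaminated, clean=trials, mixing=mixing, source=source
    )
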