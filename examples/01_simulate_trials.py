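"""Generate class-separable synthetic EEG and verify the planted effect.

Builds 20 trials per class on an 8-channel montage where the positive class
carries twice the alpha-band (8-14 Hz) power on the first four channels,
then re-estimates the band-power ratio with a Welch periodogram.
"""

import numpy as np
from scipy import signal

from eegfsel import BandEffect, SynthSpec, generate_synthetic_trials

spec = SynthSpec(
    n_trials_per_class=20,
    n_channels=8,
    fs=128.0,
    duration=8.0,
    band_effects={1: (BandEffect(8.0, 14.0, channels=(0, 1, 2, 3), factor=2.0),)},
    seed=0,
)
ts = generate_synthetic_trials(spec)
print(f"trial tensor: {ts.trials.shape} (trials x channels x samples) @ {ts.fs} Hz")
print(f"labels: {np.unique(ts.labels, return_counts=True)}")


def alpha_power(x):
    f, p = signal.welch(x, fs=ts.fs, nperseg=512)
    m = (f >= 8) & (f < 14)
    return p[m].sum() * (f[1] - f[0])


pos = ts.trials[ts.labels == 1][:, :4].reshape(-1, ts.n_samples)
neg = ts.trials[ts.labels == -1][:, :4].reshape(-1, ts.n_samples)
ratio = np.mean([alpha_power(x) for x in pos]) / np.mean([alpha_power(x) for x in neg])
print(f"estimated alpha-power ratio (class +1 / class -1): {ratio:.2f}")
print("-> close to the configured factor 2.0: the planted effect is recoverable.")
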