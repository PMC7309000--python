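"""Condition raw trials and extract the full multi-domain feature bank.

Blink artifacts are mixed into the frontal channels, removed again by
time-domain regression on the explicit EOG channel, and the 24*C + 4*P
feature matrix (statistics, band power, differential entropy, asymmetry
ratios, wavelet entropy/energy) is assembled.
"""

import numpy as np

from eegfsel import (
    PreprocConfig,
    SynthSpec,
    extract_all,
    generate_synthetic_trials,
    inject_eog,
)
from eegfsel.preprocessing import preprocess_trials

ts = generate_synthetic_trials(
    SynthSpec(n_trials_per_class=5, n_channels=30, fs=128.0, duration=4.0, seed=1)
)
contaminated = inject_eog(ts, eog_amplitude=80.0, seed=2).trials
print(f"raw: {contaminated.n_channels} channels (incl. {contaminated.eog_labels})")

clean = preprocess_trials(
    contaminated, PreprocConfig(bp_high=50.0, do_resample=False)
)
print(f"after preprocessing: {clean.n_channels} channels, EOG regressed out")

fm = extract_all(clean)
print(f"feature matrix: {fm.values.shape[0]} trials x {fm.n_features} features")
for fam, sl in fm.family_slices.items():
    print(f"  {fam:8s} columns {sl.start:4d}-{sl.stop:4d}  e.g. {fm.column_names[sl.start]}")
print("-> 30 EEG channels with 7 asymmetry pairs give 24*30 + 4*7 = 748 columns.")
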