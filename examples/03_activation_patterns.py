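"""Activation patterns: what the decoder actually reads from the scalp.

A linear classifier's weight vector mixes signal with noise-cancelling
directions; correlating its continuous (cross-validated) output with each
spectral feature gives the interpretable forward-model pattern instead.
This example compares the per-channel pattern and its maximum across the
three conditions on one simulated replicate.
"""

import numpy as np

import ssvepgrid as sg
from ssvepgrid.decoders import ShrinkageLDA
from ssvepgrid.patterns import activation_pattern, pattern_extremum

cfg = sg.SynthConfig(seed=1)
for cond in ("top_down", "intermediate", "bottom_up"):
    epochs = sg.simulate_epochs(cfg, sg.condition(cond))
    feats = sg.psd_features(epochs)
    eeg = sg.select_channels(feats, epochs.montage.eeg_channels)
    res = sg.chronological_cv(eeg, feats.labels, feats.chrono_index,
                              classifier=ShrinkageLDA())
    pat = activation_pattern(eeg, res.decision_values)
    value, channel = pattern_extremum(pat)
    top3 = np.argsort(pat.values)[-3:][::-1]
    names = [pat.channel_names[i] for i in top3]
    print(f"{cond:>12}: map maximum {value:.3f} at {channel}; "
          f"strongest channels {names}")

print()
print("The bottom-up map maximum clearly exceeds the grid-pair conditions")
print("(its frequency-class mapping is one-to-one), while intermediate and")
print("top-down separate only on averages across replicates; the strongest")
print("channels sit over the occipital cortex where the sources project.")
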