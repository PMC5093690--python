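"""Simulate one top-down session and decode it four ways.

Generates 240 five-second epochs (40 per letter class) of the top-down
condition, extracts the 5-13.5 Hz log-power features, and compares
shrinkage-LDA decoding on all 30 EEG channels, on the three occipital
channels, on the two EOG derivations, and CCA template matching — the
four accuracy series of the study design.
"""

import numpy as np

import ssvepgrid as sg
from ssvepgrid.decoders import CCAClassifier, ShrinkageLDA, make_cca_references
from ssvepgrid.features import EOG_PRESET, OCCIPITAL_PRESET

cfg = sg.SynthConfig(seed=1)
epochs = sg.simulate_epochs(cfg, sg.condition("top_down"))
feats = sg.psd_features(epochs)

results = {}
for name, subset in [("all EEG", epochs.montage.eeg_channels),
                     ("occipital", OCCIPITAL_PRESET),
                     ("EOG only", EOG_PRESET)]:
    sub = sg.select_channels(feats, subset)
    res = sg.chronological_cv(sub, feats.labels, feats.chrono_index,
                              classifier=ShrinkageLDA())
    results[f"rLDA {name}"] = res.mean_accuracy

refs = make_cca_references(epochs.n_samples, epochs.fs, sg.condition("top_down"))
res = sg.chronological_cv(epochs.data[:, :30], epochs.labels, epochs.chrono_index,
                          classifier=CCAClassifier(refs))
results["CCA all EEG"] = res.mean_accuracy

chance, _ = sg.shuffled_chance(sg.select_channels(feats, epochs.montage.eeg_channels),
                               feats.labels, feats.chrono_index, reps=5, seed=1,
                               classifier=ShrinkageLDA())
results["shuffled-label chance"] = chance

for name, acc in results.items():
    print(f"{name:>24}: {100 * acc:5.2f}%")
print()
print("rLDA on the full montage decodes the attended frequency pair well")
print("above the shuffled-label chance level; EOG stays at chance (the class")
print("is not readable from eye movements) and CCA templates struggle because")
print("every class's frequencies are physically present in every trial.")
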