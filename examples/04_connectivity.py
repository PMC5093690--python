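"""Directed connectivity with ground truth: DTF, surrogates, time reversal.

Simulates a frontal theta source driving an occipital one through a 16 ms
conduction delay, then runs the full validation chain: MVAR fit, directed
transfer function in the 5-8 Hz band, phase-randomization surrogate
significance, and the time-reversal control that separates genuine lagged
influence from volume-conduction-like artefacts.
"""

import numpy as np

from ssvepgrid.connectivity import time_reversal_check
from ssvepgrid.synth import CoupledSourceTruth, simulate_ar

truth = CoupledSourceTruth.default(coupling="F->O", strength=0.4)
sources = simulate_ar(truth, 20_000, rng=1)
names = ("F", "O")

res = time_reversal_check(sources, order=truth.coeffs.shape[0], fs=500.0,
                          n_surrogates=200, seed=1,
                          freqs=np.arange(4.0, 9.01, 0.25))
print(f"ground truth: {truth.coupling}")
for i in range(2):
    for j in range(2):
        if i == j:
            continue
        print(f"  {names[i]}<-{names[j]}: band DTF {res.band_dtf[i, j]:.3f}, "
              f"threshold {res.thresholds[i, j]:.3f}, "
              f"verdict {res.verdict[(i, j)]}")

# volume conduction control: one source mixed instantly into two channels
rng = np.random.default_rng(2)
s = simulate_ar(CoupledSourceTruth.default(coupling="none"), 20_000, rng=rng)[0]
mixed = np.vstack([s + 0.3 * rng.standard_normal(len(s)),
                   0.7 * s + 0.3 * rng.standard_normal(len(s))])
mix = time_reversal_check(mixed, order=4, fs=500.0, n_surrogates=200, seed=2,
                          freqs=np.arange(4.0, 9.01, 0.25))
print("volume-conduction control verdicts:",
      {f"{names[i]}<-{names[j]}": v for (i, j), v in mix.verdict.items()})
print()
print("The driven direction is significant and flips under time reversal")
print("(genuine); the instantaneously mixed pair must not be certified")
print("genuine, mirroring the volume-conduction control.")
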