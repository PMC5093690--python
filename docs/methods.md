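# Methods

`ssvepgrid` analyses a six-class, frequency-pair-coded SSVEP brain-machine
interface: a 6 cm grid of three horizontal lines (5, 6, 7 Hz) and three
vertical lines (5.5, 6.5, 7.5 Hz) flickers continuously while the user
covertly attends the row/column pair forming a letter shape.  Because each
single frequency belongs to two letters, only the *pair* identifies the
class — the property that makes the paradigm gaze-independent and that
defeats classical single-frequency template decoders.  The package
implements the full analysis chain on synthetic data (no recordings are
distributed): epoch simulation, spectral features, shrinkage-LDA and CCA
decoding, chronological cross-validation with empirical chance, ITR,
repeated-measures statistics, activation patterns, and directed
connectivity with surrogate and time-reversal validation.

## Synthetic epoch generator

Each 5 s trial at 500 Hz is a sum of line responses projected through
Gaussian scalp topographies centred near Oz (centres jittered per line,
spread `topo_jitter = 0.05` disc units, width `topo_width = 0.25`), plus
1/f background noise on every EEG channel, a 10 Hz alpha rhythm through a
broad posterior topography, and optional intermodulation components at the
attended pair's sum frequency.  The two EOG derivations (vEOG = Fp1 minus
suborbital, hEOG = F7 minus F8) carry class-independent artifact noise
only, so any decoding from them is a pipeline bug, not physiology.

Condition semantics:

* **top_down** — all six lines at base amplitude `a0`; the attended pair is
  enhanced to `a0 * (1 + g)`;
* **intermediate** — attended pair `a0 * (1 + g)`, task-irrelevant lines
  dimmed to `0.1 * a0` (the 1/10-luminance manipulation);
* **bottom_up** — the whole grid flickers at one class-specific frequency
  (5 … 7.5 Hz) with a single common phase: one object, coherent response.

The attentional gain `g` is drawn once per trial as
`attention_gain * Gamma(1/cv^2, cv^2)` with coefficient of variation
`gain_jitter` (default 1, i.e. exponential-like fluctuation), shared by
both attended lines.  This trial-to-trial fluctuation is the generator's
model of a fluctuating attentional state and is essential: it is
common-mode variability that no spatial or spectral weighting can average
away, so it caps single-trial top-down decodability at realistic levels
even when sensor noise is low.  With a deterministic gain there is no
parameter setting that simultaneously keeps top-down accuracy in the
intended 30–45 % band and leaves the intermediate condition's per-feature
correlations strong enough to shape its activation map.

Defaults (`SynthConfig`): `base_amp = 1` µV, `attention_gain = 0.4`,
`gain_jitter = 1.0`, `noise_pink_amp = 4.5` µV, `alpha_amp = 2` µV at
10 Hz, `intermod_amp = 0.1` µV, `eog_amp = 10` µV, 40 trials per class
(240 total), presented in randomized blocks of one trial per class so
every contiguous quarter of the session is balanced.  With these values
ten replicate simulations (seeds 0–9) give mean chronological-CV
accuracies of ≈ 35 % (top-down), ≈ 98 % (intermediate) and 100 %
(bottom-up), EOG-only decoding inside the chance band, and CCA top-down
accuracy of ≈ 26 % — the qualitative regime of the paradigm, deliberately
not a quantitative reproduction of any human dataset.

What the generator does **not** emulate: volume conduction beyond smooth
Gaussian mixing, harmonic SSVEP components, blink/saccade waveforms,
non-stationarity across the session, and between-subject variability.
Passing tests therefore demonstrate that the analysis chain behaves
correctly on data with the assumed structure, not that the effect sizes
transfer to real EEG.

## Features

Per trial and channel the mean-removed epoch is zero-padded to a 0.1 Hz
FFT grid (5 s native resolution is 0.2 Hz, on which the half-integer bins
do not fall) and log10 power (floor 1e-12) is read at 5.0, 5.5, …,
13.5 Hz — 18 bins covering the six line frequencies and the letter sum
frequencies, whose maximum (7 + 6.5 = 13.5 Hz) is exactly the band edge.
A single rectangular-window FFT of the whole epoch is the default; Hann
tapering and channel subsets (occipital Oz/O1/O2, EOG) are options.  The
normalization satisfies a Parseval identity (full-grid spectral sum =
time-domain mean square) tested to 1e-6.

## Decoders

**Shrinkage LDA.**  With 540 features (30 channels x 18 bins) and 180
training trials the pooled within-class covariance is singular; it is
shrunk toward `nu * I`, `nu = trace(S)/d`, with the analytic Ledoit-Wolf
intensity (as implemented in scikit-learn, applied to within-class-centred
data).  Scoring is shared-covariance Gaussian: `g_c(x) = w_c'x + b_c`,
`w_c = inv(S_shrunk) mu_c`, `b_c = -mu_c'w_c/2 + log pi_c`; ties break
deterministically toward the lowest class index.  `shrinkage=0` recovers
classical LDA (verified against scikit-learn's lsqr solver).

**CCA template matching.**  Per class, sinusoidal references (sine and
cosine at the class frequencies and harmonics up to order 2; both pair
frequencies for the grid conditions, the single grid frequency for
bottom-up; the sum frequency optionally) are correlated with the
30-channel epoch via the whitened-cross-covariance SVD; the class with the
largest canonical correlation wins.  Bases are rank-truncated SVD bases so
degenerate (noiseless) epochs cannot contribute numerical-null
correlations.  The implementation is checked against a brute-force
correlation maximizer to 1e-4.

The structural prediction — and the observed behaviour — is that CCA is
near chance for top-down (every class's frequencies are present in every
trial; only the pair's modest gain differs) while rLDA learns the spatial
and spectral contrast; for bottom-up, with one frequency per class, both
decode well.

## Evaluation

Chronological 4-fold CV (contiguous 180-train/60-test splits in
acquisition order, no stratification) prevents temporal leakage; the
empirical chance level repeats the identical CV with shuffled labels
(default 20 shuffles).  The exact binomial 95 % band for guessing at
n = 240 is [12.1 %, 21.7 %], and the one-sided 95 % quantile is 20.8 % —
reported in place of any closed-form chance bound.  ITR uses the Wolpaw
formula, `B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1))`, scaled by one
selection per 5 s stimulation epoch (cue and inter-trial overheads
excluded, configurable).  Statistics: one-way repeated-measures ANOVA with
Greenhouse-Geisser epsilon applied to both degrees of freedom (implemented
directly so the degenerate all-equal-columns case returns F = 0;
cross-checked against pingouin), two-tailed paired t-tests
(scipy), and Benjamini-Hochberg FDR at q = 0.2 (statsmodels).

## Activation patterns

A linear decoder's weights mix the class signal with noise-suppression
directions; the interpretable quantity is the forward-model pattern.  The
package computes the Pearson correlation across trials between each
spectral feature and each of the six class-discriminant outputs, combines
discriminants per feature by the mean absolute correlation, and averages
across the 18 bins to one value per channel.  The pipeline feeds
*cross-validated* (out-of-sample) decision values to this computation:
in-sample outputs at d = 540 >> n = 240 correlate ≈ 0.15 with *every*
feature through overfitting, swamping condition differences.

Two caveats established during development and visible in the tests.
First, with 240 trials the sampling floor of `|corr|` after the
channel-maximum is ≈ 0.08, so map maxima are interpretable only above
that.  Second, the bottom-up map maximum exceeds the grid-pair conditions
robustly per replicate (its bin↔class mapping is one-to-one, so features
align with single discriminants), but the intermediate-vs-top-down
contrast is a few thousandths at this design size and is therefore
asserted on replicate means, mirroring how such maps are averaged across
participants before comparison.

## Directed connectivity

A two-source ground-truth generator drives a "frontal" (6 Hz, AR(2),
pole radius 0.95) and an "occipital" (7 Hz) oscillator with unidirectional
coupling of strength 0.4 acting at a 16 ms conduction delay, projected to
the scalp through frontal/occipital topographies.  The delay is not
cosmetic: with near-instantaneous coupling between two sharp resonators
the cross-correlation is almost time-symmetric and no finite-order model
recovers a direction flip on reversed data.

Analysis chain: least-squares MVAR fit (channels standardized to unit
variance, making the result invariant to per-channel gains; order fixed or
BIC-selected up to 20), transfer matrix `H(f) = inv(I - sum_k A_k
e^{-2pi i f k / fs})`, normalized DTF `gamma2_ij = |H_ij|^2 / sum_m
|H_im|^2` (rows sum to one by construction), averaged over 5–8 Hz.
Significance: amplitude-preserving per-channel phase-randomization
surrogates (default 1000, p < 0.05), which preserve each channel's
spectrum while destroying cross-channel lagged structure.  Validation: the
same analysis on time-reversed data; a directed pair is **genuine** only
if it is significant, is the dominant direction (positive net band flow),
and its net flow changes sign under reversal.  Requiring dominance means
at most one of two opposite directions can be certified — reciprocal
coupling is outside this check's scope.  Instantaneous mixing of a single
source into two channels (the volume-conduction control) is flagged
spurious because its apparent flow does not flip.  On white-noise nulls
the surrogate test is calibrated at its nominal 5 % level (checked over
200 replicates); on sharply resonant nulls it is mildly anti-conservative
(~10 %), which the dominance requirement and time-reversal control absorb.

## Problem sizes and numerical choices

Replicate studies in the test suite use the full 240-trial design with ten
fixed seeds; surrogate-based checks use 100–200 surrogates and a 0.25 Hz
frequency grid restricted to the neighbourhood of the 5–8 Hz band, which
leaves band averages unchanged while keeping the full suite within a few
minutes.  The pipeline defaults (`PipelineConfig`) are 5 replicates, 20
label shuffles and 200 surrogates.  Log-power floor 1e-12; DTF grid 0.1 Hz
over 1–45 Hz when not band-restricted; MVAR stability is flagged via the
companion-matrix spectral radius rather than rejected, since
phase-randomized surrogates occasionally fit marginally unstable models.
All randomness flows from explicit seeds; the pipeline derives stage seeds
deterministically from the master seed (generator: `master*10000 +
replicate`; shuffles: `(master, 17, replicate)`), so identical
configurations produce byte-identical reports.

## Known limitations

* The generator's amplitude model is linear in luminance for the dimmed
  lines (0.1 amplitude scale); real SSVEP amplitude is compressive in
  contrast, so the intermediate condition is easier here than in human
  data.
* Activation-map contrasts between adjacent conditions are weak at desk
  scale (above); conclusions about map *shape* are limited to the
  occipital focus the forward model puts there.
* Source-space analysis is out of scope: connectivity operates on
  simulated latent sources or user-chosen virtual channels (named linear
  combinations of electrodes), an electrode-space approximation.
* The CCA reference construction (harmonics, pair vs single frequency,
  sum term) is a modelling choice exposed through configuration, not a
  fixed property of the method.
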