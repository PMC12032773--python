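# Methods

`exobci` reimplements, against synthetic data, an EEG analysis of voluntary
versus exoskeleton-guided passive hand movement in healthy subjects (HS) and
stroke patients (SP): movement-related slow-wave potentials, event-related
(de)synchronization (ERD/ERS) in six time–frequency regions of interest,
a 102-comparison statistical plan with Benjamini–Hochberg false-discovery-rate
control, and two-class decoding with CSP+LDA and a compact CNN under
within-subject and cross-subject cross-validation.

## Synthetic session generator

The generator reproduces the experimental design: 64 channels in a 10-20/10-10
layout recorded against an FCz reference (the FCz row is identically zero until
re-referencing and is recovered by the mastoid re-reference), four runs per
session (two voluntary, two passive), 80 cued trials per run (40 left / 40
right hand in randomized order), each trial a 0.5 s cue, 2 s movement and 3 s
rest (5.5 s onset-to-onset). Sampling is at 1000 Hz by default (tests and the
reproduction script use 500 Hz and reduced trial counts as their problem
sizes).

Per-subject effect magnitudes are drawn from group-level normal distributions
whose means and between-subject SDs default to the published group summary
statistics for every group × task × measure cell (slow wave, mu/beta ERD and
ERS at the contralateral (Cc) and ipsilateral (Ci) motor channels, theta at
FCz). Stroke subjects draw separate effect sets for movements of the affected
(ASP) and unaffected (USP) side; the affected-side voluntary defaults
(attenuated/absent ERD, positive or strongly variable slow wave) come from the
same published tables, so the qualitative pathology pattern is inherited
rather than separately modeled.

Injection model:

* **Slow wave** — an additive potential at the Cc/Ci motor sources with
  raised-cosine edges and a flat plateau spanning exactly the 0.4–1.9 s
  analysis window, so the windowed mean equals the injected amplitude.
* **ERD/ERS** — multiplicative amplitude envelopes on ongoing band-limited
  Gaussian oscillators (theta 3–7 Hz at FCz, mu 8–13 Hz and beta 15–28 Hz at
  C3/C4). Baseline gain is 1 (so dB baseline correction is well defined);
  plateau gains are `10^(dB/20)` of the drawn effect. Plateaus extend a margin
  beyond each ROI window sized to the Morlet temporal smearing at the band's
  lowest frequency, so the in-window dB equals the injected value.
* **Background** — 1/f (power slope 1, configurable) noise plus white sensor
  noise, independent per channel, scaled by a per-subject noise factor.
  Oscillator amplitudes (12 µV SD at the source center) set the single-trial
  SNR, which the source study does not constrain; they are chosen so band
  power at the ROI channels is dominated by the oscillator rather than the
  noise floor, making the injected dB recoverable.
* **Blinks** — a stereotyped frontal transient at a Poisson rate (default
  4/min) to exercise the artifact-removal stage.
* **Spatial mixing** — fixed Gaussian scalp maps (σ = 3.5 cm) centered on
  C3/C4/FCz rather than a forward head model. Adequate for channel-level
  analyses; no realistic volume conduction, so connectivity- or
  source-level questions are out of scope.

Everything is deterministic given (subject seed, task, run index, generator
seed). Ground truth is the drawn per-subject effect values — bookkeeping, not
re-estimation.

### What the generator does not emulate

Real EEG has spatially correlated background activity, non-Gaussian artifacts
(EMG, electrode pops, drift), subject-specific spectral peaks, and
non-stationary effect dynamics. Passing recovery tests therefore demonstrates
that the pipeline is correct and unbiased under the stated model, not that it
is robust to every property of real recordings.

### A paradigm-inherent baseline overlap

With a 5.5 s trial period, the time–frequency baseline window (−2.5 to −0.5 s)
of each trial overlaps the previous trial's post-offset ERS interval. At the
default effect sizes this inflates baseline power by ~0.01–0.05 dB, so
measured ERD/ERS values are biased by that amount relative to the injected
plateau values. Real recordings with this design share the property. The
recovery tests therefore bound the cohort bias by 10% of the injected effect
plus twice the Monte-Carlo SEM, and bound the near-zero post-offset effects
absolutely (0.1 dB) — a relative criterion is not measurable for a 0.1 dB
effect at any feasible cohort size.

## Preprocessing

Fixed order: re-reference to mean(TP9, TP10) → bad-channel interpolation
(automatic: flat or >5 SD broadband-power outliers; inverse-distance weights
over the 4 nearest good neighbors, weights summing to 1) → ICA artifact
removal → zero-phase 4th-order Butterworth band-pass (0.01–10 Hz for the
time-domain branch, 0.5–40 Hz for the time-frequency branch) → polyphase
resampling to 200 Hz → epoching into half-open [−3, 6) s windows around
movement onset (1800 samples at 200 Hz; boundary trials dropped and counted)
→ flip-merge (left-hand trials have homologous channel pairs swapped and are
pooled with right-hand trials in the right-movement frame; Cc=C3, Ci=C4).

Zero-phase filtering is used because the ROI windows depend on ERP latencies.
ICA rejection is automated: FastICA (components capped at the numerical data
rank), a component is removed when its absolute correlation with a 0.5–8 Hz
band-passed frontal-channel average exceeds 0.8. Manual component selection is
not reproducible; the threshold is configurable. The decoding branch skips
ICA/interpolation (hand-uncorrelated artifacts add only label-independent
noise) and band-passes broadly before windowing.

## ERP and time–frequency analysis

ERPs are per-condition trial means, baseline-corrected over −2 to 0 s; the
slow-wave measure is the mean amplitude over the closed 0.4–1.9 s window at
the role-mapped channel. Time–frequency maps use a complex Morlet CWT (center
frequency 1 Hz, bandwidth 1.5; scales chosen so pseudo-frequencies hit the
1–40 Hz grid at 0.5 Hz steps exactly). Single-trial power (|CWT|²) is averaged
over trials, converted to dB, and baseline-corrected by subtracting the mean
dB over −2.5 to −0.5 s per frequency and channel (equivalent to division in
linear power). Power (not amplitude) averaging is used. ROI windows are closed
intervals on the sampled grids; the beta post-offset ROI window is
task-dependent (2.6–3.6 s voluntary, 2.1–3.1 s passive). Epoch padding (±3/6 s)
leaves all ROI windows well inside the wavelet cone of influence.

## Statistics

Each report cell is a paired change-score test: the Cc and Ci columns are
two-sided one-sample t-tests of the per-subject measure against zero (the
measures are already baseline-relative), and the Cc−Ci column tests the paired
difference. The plan enumerates 3 groups × 2 tasks × (5 sensorimotor measures
× 3 contrasts + 2 theta measures at FCz) = 102 comparisons; all 102 p-values
form a single BH-FDR family and significance is decided on q < 0.05.
Zero-variance inputs yield p = 1 with a degeneracy flag instead of raising, so
null simulations always complete.

## Decoding

**CSP+LDA** — trials are band-passed 8–30 Hz, windowed 0–2 s from movement
onset at 200 Hz, restricted to 21 named channels. Class covariances are
per-trial trace-normalized and averaged (with an optional ridge, default 1e-9
of the composite trace); the generalized eigenproblem `C0 w = λ (C0+C1) w`
is solved and one eigenvector from each end of the spectrum kept (2 filters).
Features are log of sum-normalized filtered variances; the classifier is LDA.

**Compact CNN** — an EEGNet-style architecture on near-raw EEG (window −0.5 to
3 s at 200 Hz): a temporal convolution bank (F1=8 kernels, 101 samples
≈ 0.5 s), a max-norm-constrained depthwise spatial convolution over all
electrodes (D=2), and a separable convolution to F2=16 maps, each block with
batch normalization, ELU, average pooling (4 then 8) and dropout 0.5, ending
in a dense softmax. It is implemented directly on NumPy: temporal convolutions
run in the Fourier domain with hand-derived adjoints (verified against finite
differences), training is Adam on cross-entropy, fully deterministic under the
seed. Odd kernel lengths (101/17) keep 'same' convolutions symmetric. The
window is read relative to movement onset; the channel set defaults to the
full montage and is configurable.

**Schemes** — within-subject: 10 random stratified 90/10 holdouts (a strict
k-fold mode exists for partition-style audits). Cross-subject: healthy — 10
random 18-train/2-test subject splits; patients — leave-one-subject-out over
the 10 subjects. Splitters are seeded; subject identity never crosses the
train/test boundary (asserted in tests).

## Validation experiments

* **Recovery** — a 20-subject healthy passive-movement cohort (24 trials/run,
  500 Hz in the shipped configuration); pipeline estimates are compared with
  the injected per-subject ground truth, with the tolerance policy above.
* **Null controls** — with all effects zero: ≤5% of the 102 comparisons
  significant in expectation over 200 measure-level repetitions, and CSP
  left/right decoding statistically indistinguishable from 50%.
* **Passive-vs-voluntary generalization ordering** — a controlled paired
  cohort: each subject draws one standard-normal deviate per effect, scaled by
  the published voluntary SDs in one condition and the (uniformly lower)
  passive SDs in the other, with identical shared means, and both conditions
  simulate the identical run so noise and trial order are common. Averaged
  over 10 cohort seeds, cross-subject accuracy is higher for the
  passive-variability condition for both decoders — the published direction.
  The effect for CSP is small (~1–4 accuracy points: the mu/beta SD contrast
  is only ~1.3×), and single small cohort batches can reverse the CNN
  contrast when a batch's draws happen to align with the population mean;
  the reported quantity is always the across-seed mean.

## Numerical choices and degenerate inputs

Closed ROI windows include boundary samples (1e-9 tolerance against float
grids). Resampling rescales and rounds event indices. Upsampling is refused.
All-bad-channel interpolation, missing marker files, unmapped event codes,
out-of-range run indices, and frequency grids beyond Nyquist raise distinct
errors. dB conversion floors power at 1e-300 to avoid log(0) on synthetic
zeros. CSP raises a ridge-suggesting error on covariance failure; CNN training
aborts on non-finite loss.

## Known limitations

No forward head model; no EMG/kinematics; no online processing; no
between-group inference (the statistical plan, like the report tables it
mirrors, is within-group); EDF files can be read but not written (BrainVision
is the native output format); within-subject CNN accuracy at very small trial
counts is training-noise-limited.
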