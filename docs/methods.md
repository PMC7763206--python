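# Methods

This note documents the models, parameter choices and numerical conventions
behind `edanx`, in the order the pipeline runs them.

## Signal conditioning

Skin conductance must be sampled well above twice the mains frequency or the
interference folds irreversibly into the EDA band: a tone at frequency `f`
sampled at `fs` appears at `|f − fs·round(f/fs)|`, so 50.032 Hz sampled at
51.2 Hz lands at 1.168 Hz (and the second harmonic at 2.336 Hz) — right among
phasic responses. The recommended acquisition chain is therefore: sample at
512 Hz, low-pass with a linear-phase FIR filter (default 257 taps, Hamming
window, 25 Hz cutoff — ≥ 40 dB attenuation at 50 Hz, verified in the tests by
evaluating the frequency response), then decimate by 10 to the 51.2 Hz
working rate, whose Nyquist (25.6 Hz) exactly spans the feature-stage PSD
grid. An odd tap count makes the group delay `(n_taps−1)/2` an integer, so
delay compensation is an exact shift; edge samples inside the filter
transient are flagged (`fir_edge_mask`) rather than extrapolated. Decimation
keeps index-0 phase (deterministic, composable:
`decimate(x, ab) == decimate(decimate(x, a), b)`).

Recordings already at 51.2 Hz (the wearable of the motivating protocol)
bypass this chain with a warning, since any mains contamination has already
aliased and cannot be filtered out afterwards. Heart rate arrives pre-filtered
from the device (derived from PPG), so only conductance is filtered; HR is
decimated on the same grid to stay synchronized.

The sensor quality check expects a conductance rise of ≥ 0.05 µS
(configurable) within 3 s of a deep breath.

## Tonic/phasic decomposition

Conductance is modelled as `gsr(t) = scl(t) + ∫ d(τ) k(t−τ) dτ` with a
non-negative sudomotor driver `d` and the Bateman impulse response
`k(t) = exp(−t/τ_d) − exp(−t/τ_r)`, normalized to unit peak (so a driver
impulse of mass `a` yields an SCR of peak amplitude `a` µS). Defaults
τ_r = 1 s, τ_d = 3.75 s are the canonical continuous-decomposition values and
consistent with published SCR timing (1–3 s rise, 2–10 s half-recovery);
optional per-record optimization of the taus (Nelder–Mead on the driver
reconstruction residual) is off by default.

*Tonic estimate*: moving 10th-percentile baseline over a 20-s window,
smoothed by a 4-s uniform kernel. A low percentile is robust to phasic
bursts; the window length trades drift tracking against absorption of long
responses. The phasic component is defined as `scr = gsr − scl`, so
`scl + scr` reconstructs the input exactly by construction and all detection
error is confined to the event stage.

*Driver recovery*: frequency-domain division of `scr` by the kernel with
Tikhonov regularization, `D = S·K* / (|K|² + λ·max|K|²)`, then non-negativity
clipping. Default λ = 1e-4. Larger values (1e-1) were tried and rejected:
they smear each impulse over seconds, merging events 8 s apart and biasing
onsets several seconds early; 1e-4 keeps impulses sharp while the detection
stage handles the residual noise. Values below 1e-5 amplify measurement noise
faster than they sharpen.

*Event extraction*: the driver (Gaussian-smoothed, σ = 0.08 s) is scanned for
peaks above an adaptive floor — the maximum of five robust noise sigmas
(1.4826·MAD), 1% of the tallest impulse, and half the height that a response
at the significance threshold would produce (calibrated at run time by
passing one unit-amplitude SCR through the same deconvolution chain). Each
peak yields one event:

- **onset (TON)**: first sample where the raw driver exceeds 10% of the local
  cluster peak, plus the chain's systematic crossing offset (the regularized
  deconvolution spreads impulses symmetrically, so the raw crossing leads the
  true onset by ~0.5 s; the offset is self-calibrated from the same unit
  impulse response, not hand-tuned).
- **amplitude (AMP)**: the driver mass integrated over a window around the
  peak (0.5 s before to 3 s after, bounded by the valleys separating
  neighbouring clusters). For the unit-peak kernel this equals the
  trough-to-peak rise the response would show in isolation, and unlike a
  direct trough-to-peak reading it stays accurate when a small response rides
  the decay of a large predecessor (where the summed signal never stops
  falling). Events with onsets under 1 s apart are merged and their masses
  summed (superposition); events below 0.05 µS — the conventional
  significance threshold — are dropped.

The round-trip property (forward-simulate tonic + SCR train, decompose,
compare) is exercised in the test suite: exact event counts and amplitude
RMSE within 10% of the mean true amplitude in the low-noise regime, onsets
within 0.5 s.

Degenerate inputs: an all-constant trace returns `scl = gsr`, zero phasic
component and no events; traces shorter than 10 s are rejected (no stable
tonic estimate).

## Windowing and features

Each rated stimulus defines one half-open window `[t − 5 s, t)` — strictly
pre-stimulus, excluding the pickup sample itself, since the rating panel
appears at the stimulus and the preceding seconds carry the maximal phobic
exposure. Windows may overlap if events are closer than 5 s (logged, not an
error); events whose window would precede the recording start are skipped
with a warning. At 51.2 Hz a window holds 256 samples.

The 32 features per window, in canonical column order:

- `{GSR,SCL,SCR} × {mav, mar, std, wl, ssc, wamp}` (18): mean absolute
  value; MAV relative to the session baseline MAV (`X_B`, computed once per
  subject over the 60-s resting baseline — MAR removes inter-individual
  conductance offsets); sample standard deviation (N−1); waveform length as
  the sum of *squared* first differences (the package keeps this squared
  form; `wl_absolute=True` switches to the conventional Σ|Δx|); slope-sign
  changes with a 0.001 µS deadband on both adjacent slopes; Willison
  amplitude with a 0.5 µS step threshold.
- `GSR_nr, GSR_avra, GSR_maxra` (3): count, mean and max amplitude of the
  SCR events whose onsets fall in the window; with zero events the amplitude
  statistics are 0 (no response = minimal response, keeping vectors finite).
- `{GSR,SCL,SCR} × {fmd, fmn}` (6): median and mean frequency of a
  zero-padded periodogram. A 1024-point transform at 51.2 Hz puts bins at
  exactly 0, 0.05, …, 25.6 Hz (513 points); scaling satisfies Parseval (the
  one-sided powers sum to the mean squared value, tested against white
  noise). The median index minimizes `|Σ_{k<M} P_k − Σ_{k≥M} P_k|`; ties
  resolve to the largest M whose left mass does not exceed half the total,
  so a single-bin spectrum reports that bin. A phasic stream that is
  identically zero has no spectrum; its FMD/FMN are reported as 0 Hz rather
  than raising inside a batch extraction.
- `HR_mav, HR_std` (2): over the window's HR vector, with 1/P and 1/(P−1)
  normalization for the P HR samples.
- `HR_lfi, HR_hfi, HR_hlr` (3): mean squared value of the HR signal
  band-passed to 0.04–0.15 Hz (LF) and 0.15–0.4 Hz (HF) by 3rd-order
  Butterworth filters, and their ratio HFI/LFI. The filters run causally
  (single pass — real-time compatible) in second-order-section form, because
  at 51.2 Hz the corner frequencies sit three decades below Nyquist and the
  transfer-function form is numerically unusable; initial conditions are
  matched to the window's first sample to shorten the start-up transient.
  With zero LF intensity the standalone ratio raises; batch extraction
  reports 0.

A 5-s window cannot resolve the 0.04 Hz edge of the LF band (period 25 s);
the band features are still computed as defined — they act as short-window
proxies, and this limitation is inherited from the protocol, not fixable
here.

## Estimator

The anxiety estimate is a full quadratic in a P-feature subset
(`P(P+1)/2 + P + 1` coefficients; design terms ordered: products `x_i x_j`
for i ≤ j lexicographically, linear terms, intercept). Coefficients are the
least-squares minimizer of `S = Σ (ANX − ANX*)²` via `lstsq`; rank-deficient
designs return the minimum-norm solution so an enumeration over millions of
subsets never aborts.

*Split*: the identification/validation partition is stratified by reported
level — level k with N_k occurrences contributes `round(6/7 · N_k)` rows to
identification (halves away from zero; the convention is fixed for
determinism), membership drawn uniformly under a seed. For the level totals
[41, 16, 12, 9, 7, 4, 4, 2, 5, 2, 3] this yields identification counts
[35, 14, 10, 8, 6, 3, 3, 2, 4, 2, 3] and 90/15 set sizes.

*Search*: every C(32, P) subset is fitted on the identification set only;
the subset with minimal S wins, ties going to the lexicographically first
subset in canonical feature order (deterministic across platforms and
execution strategies); the winner's validation-set S is then reported.
Because any smaller model embeds in a larger one with zero coefficients, the
best identification S is non-increasing in P (tested against an independent
naive enumerator). The per-P report emits both S and S/N. Searches with
P ≤ 3 over all 32 features run in seconds; P = 7 (3 365 856 subsets) is a
documented long-running mode, not part of the default runs.

*Classification*: estimates are real-valued and unclamped; thresholding maps
(−∞, 5] → low, (5, ∞) → high for 2 classes and (−∞, 3] / (3, 7] / (7, ∞)
for 3 classes (closed upper bounds, extreme intervals extended so every
estimate has exactly one class). In the pipeline, estimates are rounded to
9 decimals before thresholding: integer ratings reproduced to machine
precision otherwise land a float ulp above a boundary and flip class; the
rounding cannot affect any estimate genuinely away from a boundary.
Confusion matrices are row-normalized with empty true classes flagged (NaN
row) rather than silently renormalized; overall accuracy is
100·trace/total.

## Synthetic cohort generator

`edanx.synth` emulates the acquisition conditions the protocol was designed
for; its defaults are the study conditions, not tuning knobs:

- 7 subjects × 15 rated events, events 20 s apart after a 20-s lead-in;
  60-s resting baseline per subject; 51.2 Hz.
- Latent anxiety: piecewise-constant episodes (one per event, mimicking
  exposure floors); SUD = round(latent + uniform(−0.5, 0.5) reporting
  noise), clamped to 0–10. The cohort's rating histogram is
  [41, 16, 12, 9, 7, 4, 4, 2, 5, 2, 3] by default (the motivating study's
  marginal), shuffled across subjects under the seed; other histograms are
  validated for feasibility.
- EDA: tonic level 6 µS, mean-reverting random walk (0.05 µS/√s, smoothed to
  the minutes-scale wander of a real conductance level) clipped to the
  physiological 2–20 µS range; SCRs from an inhomogeneous Poisson process
  whose rate interpolates 2/min (rest) → 20/min (anxiety 10), amplitudes
  growing with anxiety within 0.1–3 µS; optional mains interference at
  50.032 Hz + harmonics (1/k amplitude decay, default 0.02 µS) and 0.01 µS
  measurement noise.
- HR: 65 bpm base + 3 bpm per anxiety unit, LF (0.1 Hz, 1.5 bpm) and HF
  (0.25 Hz, 2 bpm at rest) oscillations with the HF amplitude shrinking
  linearly with anxiety (vagal withdrawal), plus 0.3 bpm noise.
- All draws flow from one `SeedSequence`; identical seeds give bit-identical
  cohorts. `SessionConfig.noiseless()` silences every noise source for
  recovery tests.

The anxiety→physiology link is generative while the estimator inverts it
from features computed on the signals alone, so recovery tests are not
circular. What the generator does **not** emulate: motion artifacts,
electrode drift/detachment, realistic PPG waveforms, respiratory sinus
arrhythmia beyond a single HF tone, inter-subject variability in SCR shape,
or any coupling between EDA and HR beyond the shared latent state. Passing
tests therefore demonstrate that the chain is self-consistent and recovers
known ground truth under clean-to-moderately-noisy conditions — not that it
reaches any particular accuracy on clinical data.

## Problem sizes in the default runs

The test suite and the acceptance script run the full chain on 7×15 cohorts
(105 windows), subset searches up to P = 3 over all 32 features (5 488
least-squares fits), 20-replicate recovery experiments, and 1000-vector
feature oracles; everything completes in well under a minute on one core.
Larger searches scale combinatorially and are left to the user.

## Known limitations

- The decomposition is non-causal (percentile baseline and FFT deconvolution
  look ahead); the streaming estimator sidesteps this with a rolling 30-s
  context buffer, which delays tonic adaptation near the buffer edge.
- Driver-mass amplitudes inherit a small positive bias from clipped noise
  mass inside the integration window (visible as a few percent on small
  events at 0.01 µS noise).
- Tonic drift faster than the 20-s baseline window leaks into the phasic
  component and can register as spontaneous (NS-SCR-like) events — a genuine
  ambiguity of EDA analysis, not resolvable without stronger priors.
- With 105 rows, quadratic models beyond P ≈ 5 approach interpolation on the
  identification set; validation-set S is reported precisely to expose such
  overfitting.
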