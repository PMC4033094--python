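# Methods

This note documents the models, numerical choices, and limitations of the
`nirsbci` pipeline in the package's own terms.  Every number quoted here
is computed by the test suite or by `scripts/acceptance.py`.

## Signal model

### Hemodynamic response

A task-evoked cortical activation is modeled as a unit-peak kernel
convolved with the task boxcar.  The kernel is a single-gamma main lobe
(shape 6, scaled so its mode falls `time_to_peak` seconds after the
response starts), shifted right by `onset_lag`, minus a smaller gamma
undershoot whose lobe begins exactly at the main peak (so it can never
move the peak sample) and bottoms out near 2 × `time_to_peak`.  Defaults:
onset lag 1.5 s, time to peak 6 s, undershoot fraction 0.1 — consistent
with responses that lag stimulus onset by 1–2 s and peak 4–8 s after it.
The convolution is normalized by the kernel sum so sustained activation
plateaus at `hbo_amplitude` (default 1 µM).

Two deliberate numerical choices:

* **Compact support.** The gamma tail is zeroed once it falls below 10⁻⁴
  of peak.  Without this, a residual of order 10⁻⁶ µM leaks across the
  30 s fixation gap into the next trial; in a noise-free world the
  learned thresholding baseline is then a float-epsilon quantity and
  onset "detections" at 0 s latency appear depending on trial order.
* **Peak sample exactness.** The kernel attains its maximum exactly once,
  at sample `round((onset_lag + time_to_peak)·rate)`.

`hb_to_hbo_ratio` (default −1/3) maps the HbO response onto Hb as a
negative scalar multiple — the anticorrelation that CBSI assumes.
`lateralization` ∈ [0, 1] sets the right channel's gain to
`1 − lateralization` (left gain 1).  The default 1.0 routes the entire
response to the left channel so the bilateral difference used by the
thresholding detector carries the full signal; the detector is
meaningless without some asymmetry (with a symmetric response the
difference is signal-free, and in a noise-free world onset detection
becomes impossible).

### Noise and motion

Physiological noise is added per channel and chromophore as seeded
sinusoids with random phase: cardiac (1.2 Hz, 0.4 µM), respiration
(0.3 Hz, 0.3 µM), Mayer waves (0.1 Hz, 0.2 µM); plus a Gaussian
random-walk drift low-passed below 0.004 Hz and rescaled to 1 µM SD, and
white noise at 0.15 µM SD.  No amplitude or SNR figures exist for the
instrument being emulated, so these are stated choices at the scale of
typical prefrontal fNIRS recordings (task responses of order 1 µM,
physiological oscillations a few tenths of µM), fixed once and not tuned
against any downstream result.

Motion artifacts are spikes (one-sample rise, exponential decay with
τ = 0.5 s) and baseline shifts (steps), Poisson-distributed in time with
random sign, added *identically* to a channel's HbO and Hb
(`common_mode`, default on) — exactly the artifact structure CBSI is
designed to remove.  Defaults for an unrestricted-mobility block: spikes
2/min at 5 µM, shifts 0.5/min at 3 µM; a restricted block has none.

Inter-participant variability: per participant, an amplitude gain drawn
lognormal(0, 0.25) and an onset lag uniform in [1, 2] s.  There is *no*
trial-to-trial response variability within a participant; the
consequences are discussed under Limitations.

## MBLL conversion

`forward_optics` and `mbll_invert` implement the modified Beer-Lambert
Law as an exact 2×2 linear system per channel and sample, with molar
extinction coefficients interpolated from a bundled subset of the
published Gratzer–Kollias compilation (650–900 nm), source–detector
separation 3 cm and DPF 6.0 at both wavelengths (defaults 690/830 nm —
typical values; the instrument's true constants are not public, and every
property that matters downstream is a round trip insensitive to them).
Wavelength pairs whose extinction matrix has condition number above 10⁶
are rejected with an error naming the pair.  Round-trip identity holds to
better than 10⁻⁹ µM.

## Filtering chain

Order: detrend → smooth → CBSI, applied to whole continuous block
recordings (a 0.01 Hz filter has no meaning on a 30 s trial); trials are
sliced out afterwards.  Channels are never mixed.

* **Window design.** Savitzky-Golay filters are parameterized here by a
  −3 dB cutoff, which they do not natively have.  The empirical
  approximation f_c·Δt ≈ (p+1)/(3.2·W − 4.6) seeds the window length, but
  at polynomial degree 1 (where the smoother reduces to a moving average)
  it mispredicts the realized cutoff by ~30%, so the window is refined
  against the numerically measured transfer function; the realized
  −3 dB frequency is logged in provenance.  At 6.25 Hz: 0.15 Hz → 19
  samples (realized 0.146 Hz), 0.01 Hz → 277 samples (realized
  0.0100 Hz).  Edges are mirror-padded.
* **Near-idempotence caveat.** A second detrending pass changes signal
  content above ~0.4 Hz by well under 1% RMS, but the degree-1 design's
  sidelobes decay only as 1/f, so content in the 0.003–0.4 Hz range
  (e.g. the drift default, or the block-design fundamental at 1/120 Hz)
  is only partially removed per pass.
* **CBSI.** With mean-centered x = HbO, y = Hb and α = sd(x)/sd(y):
  HbO′ = (x − αy)/2, Hb′ = −HbO′/α.  The output pair is exactly
  anticorrelated by construction.  α is computed per channel over the
  whole block, as the method defines it.  Zero-variance channels skip
  CBSI with a warning rather than aborting a batch.  Note CBSI rescales
  the true response by (1 + α/α₀)/2 (α₀ = −HbO/Hb ratio), so corrected
  amplitudes are not in original units.

## Classifiers

All three models emit a timestamped task/rest label series consumed by
one scoring path.  Trial spans are half-open `[onset, onset + duration)`
with `floor(duration·rate)` samples from the first sample at/after onset
— a 30 s trial at 6.25 Hz contributes 187 samples, and the two-channel
window vector is 187 × 4 = 748 long.  Thresholding uses strict
exceedance (ties → rest).  SVMs are linear, C = 1, fitted by libsvm's
SMO on per-feature standardized inputs (standardization fitted on
training rows only and stored in the model); whether the original
pointwise model standardized is unknown, so it is on by default and
switchable.  On continuous data the window model slides causally with a
1 s stride, stamping each label at the window's final sample.  Onset
latency is the first task-labeled sample at/after trial onset (a
persistence parameter exists, default 1 sample).  Trials shorter than
the window are an error unless truncation to the shortest trial is
requested.

## Evaluation protocol

Nine-fold cross-validation holds out one task and one rest trial per
fold (the source protocol is described both as nine- and ten-fold; nine
matches the 9 + 9 trial structure and is the default, with k exposed).
Accuracy pools timepoint labels (window model: one label per trial).
Group inference is a one-tailed one-sample t vs. chance 0.5 — the
critical value at df = 39 is 1.68 — with a documented zero-variance
limit path (t = ±∞).  Per-participant significance is an exact one-tailed
binomial test on trial-level majority-vote outcomes (timepoint counts
would be anticonservative under autocorrelation; ties score as wrong).
Model pairs are compared by paired two-tailed t-tests.  For the
realistic block (rest/task/rest, 210 s each) the majority-class baseline
(2/3) is reported alongside accuracy, and no multiple-testing correction
is applied across the three models.

## What the simulator does and does not establish

The generator reproduces the *statistical structure the analysis
assumes*: sampling geometry, block paradigms, a lagged peaked response,
HbO/Hb anticorrelation, band-limited physiological noise, and
common-mode motion.  Three idealizations matter when reading green
tests:

1. **Motion is perfectly common-mode**, so CBSI removes it almost
   exactly (α → 1 as artifacts dominate).  Consequently unrestricted
   training barely degrades any model here, whereas real artifacts are
   only imperfectly shared between chromophores.
2. **No trial-to-trial response variability.**  A participant's 16
   training trials are near-replicas up to noise, so the 748-dimensional
   window SVM separates them essentially perfectly and reaches ceiling —
   the small-sample/high-dimension fragility that this model family
   shows on real recordings does not emerge, and the expected accuracy
   ordering (pointwise above window) and the mobility-degradation
   pattern do not reproduce in this world.
3. **Full lateralization by default**, so the bilateral difference
   carries the entire response and the thresholding detector performs
   well above chance — on real data, bilateral activation leaks into the
   reference channel and pushes it to chance.

Onset-latency behavior, by contrast, is driven by the response shape
itself and transfers: noise-free detections fall within
[onset lag, onset lag + time to peak], and under default noise the
simulated thresholding latency (≈ 12 ± 2 s across cohorts) sits in the
physiologically expected 9–13 s range.

## Degenerate inputs and tie-breaks

Rejected with errors: non-positive durations, overlapping or unsorted
trials, series shorter than the filter window (the error states the
minimum duration), zero-variance Hb in CBSI, single-class SVM fits,
k not dividing the per-class trial counts (the error proposes valid k),
geometry mismatches between model and recording (expected vs. actual
named), out-of-range wavelengths, ill-conditioned extinction matrices.
Handled without errors: zero-variance channels in the pipeline (skip
CBSI, warn), empty trial tables (empty featurization/predictions), the
zero-variance paths of the t statistics, majority-vote ties (scored
against the participant).
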