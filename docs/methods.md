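# Methods

This note records the modeling and numerical decisions behind `nasemg`:
what each stage assumes, which parameters matter and why their defaults
were chosen, what the synthetic scenarios do and do not emulate, and the
known limitations.

## The measurement model

The pipeline assumes a paired acquisition: the same utterances produced
once under RT-MRI (images at 14 frames/s plus 16 kHz audio) and once under
surface EMG (5 channels at 600 Hz plus 8 kHz audio), by the same speaker,
with an unknown smooth monotone time warp between the two sessions.  Three
further assumptions carry the method:

- the airway area between velum and pharyngeal wall, measured as a
  hypo-intense pixel count inside a fixed ROI, is monotone in velum
  aperture, so its normalized curve x(n) indexes the velopharyngeal port;
- the audio tracks share enough energy landmarks that DTW can recover the
  inter-session warp to well under the MRI frame period's order of
  magnitude;
- muscle activity related to the velopharyngeal gesture lies inside the
  *nasal zones* — the thresholded aperture intervals widened to include
  the lowering and raising transitions — which is exactly why the zone
  boundaries are extended geometrically rather than taken at the
  threshold crossings.

## Stage-by-stage choices

### Sagittal / coronal segmentation (`mri`)

Region growing over `intensity < threshold` restricted to the ROI is the
seed's connected component under (t, y, x) 6-connectivity, computed with
`scipy.ndimage.label`.  The temporal face-adjacency is what lets a single
seed propagate across frames.  The hypo-intensity threshold (default 0.5
of the normalized intensity range) and the connectivity are exposed as
parameters: the original interactive seeding protocol does not state
either, so they are user-visible knobs, not baked-in truths.  Coronal
sequences take a configurable intensity polarity (`dark` airway or
`bright` cavity) because rendered cavity contrast differs between
acquisitions.  σ of the normalized curve is the *population* SD (divide by
N) — fixed for reproducibility.  A constant area curve is flagged
`degenerate`: no nasality is detectable and downstream stages refuse it
explicitly rather than emitting arbitrary zones.

### Alignment (`align`)

DTW runs on short-time log-energy envelopes (25 ms window, 10 ms hop,
floor −60 dB) of both tracks resampled to 12 kHz, not on raw samples:
sample-level DTW is O(N²)-prohibitive at 12 kHz and phase-fragile, and
energy landmarks are what the two sessions genuinely share.  Local cost is
the squared envelope difference; steps are {(1,1), (1,0), (0,1)} with
ties broken (1,1) ≻ (1,0) ≻ (0,1) for determinism.  The Sakoe–Chiba band
(default 10% of the longer timeline) is expressed in *normalized*
coordinates, |i/(n−1) − j/(m−1)| ≤ w, which makes the admissible region
exactly transpose-symmetric — the minimal cost is therefore invariant
under argument swap, a property the tests check exactly.  The
many-to-one path is collapsed to a single-valued time map by the median
matched index per reference frame, with monotonicity enforced by a
running maximum; the warped curve is resampled onto the 600 Hz EMG clock
by linear interpolation, which cannot overshoot the curve's range.

### Zoning (`zoning`)

The curve is min–max renormalized after warping (thresholding is defined
on a normalized signal), then thresholded at τ = x̄ + σ/2.  The mirrored-
angle construction is formalized as: θ₁ is measured at the peak between
the vertical axis and the peak→(x = x̄ crossing) segment; the congruent
triangle drops from the crossing level x̄ to 0, giving the horizontal
extension v₂ = x̄·|t_c − t_p|/(y_p − x̄), applied outward on each side.
The figure this construction comes from admits other readings; this one
is fixed and unit-tested (peak (1.0 s, 1.0), crossing (1.5 s, 0.5) →
boundary 2.0 s; x̄ = 0 → no extension).  Two robustness rules matter in
practice:

- candidate τ-runs that share the same adjacent x = x̄ crossings are
  grouped before peak selection — noise can split one nasal event into
  several runs, and a one-sample fragment would otherwise anchor a wild
  extension on a barely-above-threshold "peak";
- local maxima must have prominence ≥ σ/2 (the threshold margin), with
  plateaus contributing their midpoint; the first qualifying maximum
  anchors the rising geometry and the last the falling one, which is what
  handles velum-stays-open-long events.

Zones are half-open [start, end) on the EMG clock; frames are labeled by
the zone containing their temporal midpoint (unbiased, order-independent,
cheap — a majority-of-samples rule would differ only for boundary frames).

### EMG processing and features (`emg`, `features`)

Pre-processing per channel: max-absolute normalization (preserves the
zero baseline needed before rectification), absolute value, and a
12-point moving average run forward and backward (net 23-tap symmetric
response) with reflect padding — an even-length single-pass boxcar cannot
be zero-phase on the sample grid.  Frames are 100 ms with a 20 ms shift;
the trailing partial frame is discarded.

Classification features are computed on the normalized **raw** signal by
default (`features_on="raw"`), keeping zero-crossing rate and kurtosis
informative; the rectified/smoothed envelope is selectable because it is
not documented which representation the original classifier consumed.
Feature conventions, fixed and oracle-tested: population SD; excess
(Fisher) kurtosis with the population estimator, 0 for zero-variance
frames; energy as mean of squares (length-invariant); ZCR counts sign
changes with zeros inheriting the previous sign, divided by L−1; mean
absolute slope Σ|Δx|/(L−1).

### Classification (`classify`)

Stratified frame-level 10-fold CV with seeded shuffling; features are
standardized on each training fold; SVM-RBF with C = 1 and γ = 1/(d·var)
(the original study's hyperparameters are unstated, so these sklearn
defaults are exposed in the config rather than hidden).  Confidence
intervals are Student-t over folds: mean ± t₀.₀₂₅,ₖ₋₁·s/√k.  Reported
percentages round half-up to one decimal.  Frame-level pooling lets
adjacent overlapping frames straddle folds; this leakage inflates
apparent accuracy whenever features autocorrelate over 100 ms — visible
in the synthetic SNR-0 condition, where error sits below the ~50% chance
level for exactly this reason.  Utterance-level grouping would remove it
but departs from the frame-pooled protocol being reproduced; the
per-fold metrics are exported so either analysis can be run downstream.
Zone-majority voting predicts nasal iff nasal-predicted frames are ≥
non-nasal ones (ties to nasal, per the stated rule), with optional
[a%, b%] part restriction; zones left without frame midpoints are skipped
with a warning rather than silently counted.

### Mutual information (`infometrics`)

Plug-in estimate over an equal-width 16-bin joint histogram (each
signal's observed range), log base 2, empty cells contributing zero;
normalization I/√(H(X)H(Y)) by default with I/min(H) and 2I/(Hx+Hy)
selectable.  The plug-in estimator is biased upward by roughly
(occupied cells)/(2N·ln 2), and the bias depends on the marginal shape:
nasal-zone velum samples span [0, 1] while non-nasal samples concentrate
near 0, so the two classes have *different bias floors* and their MI
values are not directly comparable at small N.  Consequently the noise
null is tested as "both classes sit within the bias floor (raw MI ≤ 0.1
bits, normalized ≤ 0.05)" rather than as distributional overlap, and
cross-class comparisons on real data should be read directionally, not
as effect sizes.

## The synthetic scenarios

`synthetic` generates the study conditions end to end from one seeded
generator (bit-reproducible): raised-cosine aperture pulses of height 1
(overlaps merged by pointwise maximum); EMG as Gaussian baseline noise
plus Hann-enveloped 60–200 Hz band-limited stochastic bursts, mixed by a
crosstalk matrix (identity + 0.15/0.05 first/second-neighbor leakage);
tone-complex "syllables" (three harmonics on an event-cycled fundamental)
as audio landmarks; toy image stacks whose dark-region pixel count is an
affine function of the aperture.

Reference conditions and why: every utterance carries one of the five
nasal vowels (the corpus design analysed utterances containing nasal
vowels; the non-nasal class is the surrounding material), period 1.4 s,
open duration 0.8 s — with the σ/2 threshold and boundary extension this
geometry yields a roughly balanced nasal/non-nasal frame split, which is
what the chance-level comparisons presume.  Burst SNR defaults to 4.
The 0.10 s activation lead is a free simulation parameter: no
quantitative EMG-to-movement lead time is established for this gesture.
The opening burst starts `burst_lead` before the pulse onset; the burst
duration (0.40 s) spans the transitional movement — the same transitions
the zone extension is designed to include, and the reason nasal zones
carry EMG correlates at all.  The optional closing burst spans the
raising movement and ends at the pulse offset (activity precedes the
*completion* of closure; anchoring it to start at the offset would put
the raising gesture's activity after the port has closed).

What the generator does **not** emulate: speech acoustics (tone complexes
only), physiological motor-unit statistics, electrode-skin artifacts,
session-to-session electrode displacement, jaw/tongue crosstalk
correlated with the linguistic material, and inter-speaker variability.
Passing the synthetic suite therefore demonstrates that the *pipeline*
recovers what it is designed to recover under its stated statistical
assumptions — it does not predict real-corpus error rates, which depend
on recorded signals and unstated classifier settings.

## Problem sizes

The reference end-to-end condition is 40 utterances (~57 s per modality,
≈2 800 frames per channel); alignment recovery uses 10 seeds of 6
utterances with random piecewise-linear warps; the SNR sweep uses 10
utterances per (SNR, seed).  These sizes were chosen so the whole
analysis, including cross-validation, runs comfortably on a single CPU
while keeping the per-class frame counts in the thousands.

## Known limitations

- The boundary-extension geometry is one consistent reading of an
  ambiguous construction; alternatives would shift zone edges by
  O(v₂) ≈ tens of milliseconds.
- DTW on energy envelopes has no discriminative power inside silence;
  the time map there is interpolated between landmarks.
- The deposited-corpus adapter (`io.read_deposited_corpus`) is
  best-effort: it round-trips directories written by this package and
  scans tolerantly otherwise, but the archive's exact internal layout is
  not specified, so no analysis here depends on it.
- Nasal consonants are out of scope (no imaging ground truth for them);
  so are acquisition hardware concerns, powerline filtering and artifact
  rejection.
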