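# Methods

This note documents the models, numerical choices and limitations of the
LCOD scorer in enough detail to audit or extend it.

## The detection model

A radial intensity profile `y` (90 samples from the disk center of
gravity to the disk edge) is modelled per spoke as

```
y = H b + P c + e
```

where `H` (90×3) holds binary indicator columns for the three holes of
the spoke on the profile grid and `P` (90×3) is a discrete orthonormal
polynomial basis of degree 0–2. Sample `j` sits at radius
`r_j = j·L/89`, `L` being the truncation radius of the ray (≈ 43–45 mm
for a well-segmented disk), so one sample covers ≈ 0.5 mm. Indicator `i`
is 1 iff `|r_j − c_i| ≤ d/2` with hole centers `c = (12.5, 25, 38) mm`
and the spoke's diameter `d(k) = 7 − (k−1)·(7−1.5)/9 mm` — the linear
clockwise progression of the insert. Boundary samples are not
fractionally weighted; at the 0.5 mm grid the induced error is far below
the noise level.

`b` is estimated by ordinary least squares (QR factorization). A hole is
detected when its coefficient differs from zero by a two-sided Student-t
test with `dof = 90 − 6 = 84`. The polynomial columns absorb smooth
intensity non-uniformity (bias fields, coil shading); they enter the
design rather than being pre-subtracted, which is equivalent up to column
span and needs a single solve.

### Why the standard errors are AR(1)-corrected

The profile grid (0.5 mm) is finer than the acquired pixels (≈ 0.98 mm
for a 256 matrix over 250 mm), and profile values are bilinear
interpolations, so neighbouring samples share source pixels and their
noise is serially correlated. Under the classical iid formula the null
distribution of t is wider than Student-t by a factor ≈ 1.7, which we
verified by Monte-Carlo on zero-contrast phantoms: the per-hole false
rejection rate after BH was ≈ 0.5 instead of ≤ 0.0125. The default
`error_model="ar1"` therefore keeps the OLS betas but estimates
`Var(b̂) = σ² (X'X)⁻¹ X'RX (X'X)⁻¹` with `R_ij = ρ^|i−j|` and ρ the
lag-1 autocorrelation of the fit residuals (clipped to [0, 0.98]; the
lagged Gram matrices are computed once per design via FFT
cross-correlation). `error_model="iid"` restores the textbook formula;
`fit_spoke_glm` defaults to it so the primitive matches the classical
definition when used standalone, while the scoring pipeline defaults to
`ar1`. With the correction, the measured null per-hole false-rejection
proportion is ≈ 0.006 ≤ q = 0.0125 (500 simulated zero-contrast slices),
with no false spoke passes in 5 000 spokes.

If the residual sum of squares is exactly zero (noise-free fixtures), a
nonzero hole beta gets p = 0 and a zero beta p = 1 — the limit of
vanishing noise.

### Geometric search and the rigid-rotation consensus

Phantom placement is never perfect, so each spoke is evaluated over a
±8° angle window (0.5° steps) around its nominal angle and over integer
profile shifts of −5…+5 samples, selecting the candidate that maximizes
the minimum per-hole |t| (the pass rule is a conjunction, so the weakest
hole governs). Left free per spoke, this 363-candidate search is itself a
multiple-comparisons problem and roughly doubled the null rejection rate.
Because the phantom rotates as a rigid body, the per-spoke selected
offsets are reduced to their median — one consensus rotation per slice —
and every spoke is re-tested at that single angle (the per-spoke jitter
search is kept: it compensates local distortion and residual COG error,
and its contribution to selection optimism measured below q). The
consensus step is switchable off (`rotation_consensus=False`) to recover
the free per-spoke search. No additional analytic multiplicity correction
is applied to the selected p-values; the residual optimism is accepted
and quantified by the null Monte-Carlo in the test suite.

On high-SNR synthetic volumes the score is unchanged for rotations up to
the 2.5°-grid points inside the search window (0–7.5°) and degrades at
10°, which exceeds the ±8° window.

### Multiple-testing structure

The family-wise level α = 0.05 is Bonferroni-split across the four LCOD
slices: 0.0125 per slice. Within a slice the 30 selected hole p-values
are adjusted by the Benjamini–Hochberg step-up rule at q = 0.0125
(`statsmodels.multipletests`). The tested hypotheses are the holes; a
spoke-level pool (10 p-values, each the spoke's weakest hole) is
available via `bh_pool="spokes"`. Scoring counts every passing spoke by
default (`all-passing`); the ACR manual's stop-at-first-failure
convention is available as `scoring_mode="acr-consecutive"`.

## Segmentation and profiling

Otsu's threshold (256 bins) on the [0, 1]-normalized slice separates
phantom from background; connected components are labelled and the
component nearest the image center whose equivalent radius
`sqrt(area/π)` lies within ±20 % of the nominal 45 mm disk radius is
kept (ties broken by radius match, then larger area). Holes are filled
before the centroid is taken so the contrast holes cannot bias the COG.

Rays step at half the pixel pitch (Nyquist-safe) with bilinear
interpolation. A sample is accepted only while its full bilinear support
lies inside the mask *eroded by one pixel*: Otsu keeps partial-volume
boundary pixels in the mask, and a single edge sample that blends disk
and membrane intensity was measured to inflate the residual variance by
an order of magnitude. The raw trace is linearly resampled onto 90
evenly spaced points spanning [0, L]. Jitter shifts replicate the
boundary value rather than injecting zeros that would mimic contrast.

## SNR

`SNR = mean(central ROI of slice 7) / SD(pooled corner boxes)`, with the
ROI a centered disk of half the segmented phantom radius and four corner
boxes of side width/16, shrunk toward the corners if they touch the
phantom. Native intensities are used, so the ratio is invariant to
multiplicative rescaling; a noise-free image returns +inf with a warning.

## The synthetic phantom

The generator renders what the detector assumes, at the reference
acquisition geometry (256×256, 250 mm FOV): a 95 mm-radius phantom body
at intensity 0.6, an inner 45 mm contrast disk separated by a 3 mm dark
membrane ring (10 % of background), and the 30 holes at
`background·(1 + contrast)` (hyperintense by default, switchable).
Rendering is anti-aliased by 4×4 sub-pixel coverage averaging — a 1.5 mm
hole is only ≈ 1.5 px wide and hard binarisation would alias it away.
Per-slice contrasts default to the nominal 1.4/2.5/3.6/5.1 %; the default
SNR of 300 sits mid-range of typical clinical head-coil phantom scans
(roughly 100–450). Noise is additive Gaussian with σ = background/SNR
(Rician magnitude optional; at these SNRs the two are indistinguishable),
drawn from a per-slice stream `default_rng([seed, slice_index])` so
volumes are bitwise reproducible. Rotation/translation move the hole
pattern/phantom; bandwidth-style stress is emulated purely as a noise
level change; a 2nd-order multiplicative polynomial bias field emulates
disabled pre-scan normalization.

What the simulator does **not** model: k-space truncation (Gibbs
ringing), ghosting, nonlinear geometric distortion, partial-volume
through-plane effects, structured coil noise, or the true (unpublished)
per-slice spoke-1 orientations of the physical insert — the default
assumes 90° (3 o'clock) on every slice and is user-overridable. Passing
tests therefore demonstrate the pipeline's statistical calibration and
geometric robustness under idealized imaging, not performance on any
particular scanner.

## Agreement statistics

For validating a scorer against raters: squared-weight Cohen's kappa
(`sklearn`, full declared category range so chance expectation is
correct; identical constant ratings define kappa = 1 with a warning),
Krippendorff's alpha with the interval (squared-difference) metric via
the coincidence matrix (missing entries allowed) — interval chosen to
parallel the squared kappa weights —, one-way random-effects ICC(1) with
the F-bound 95 % CI (MSW = 0 defines ICC = 1 with a degenerate CI), and
Bland–Altman mean ± 1.96 SD limits. For two raters with complete data,
alpha and squared-weight kappa agree up to a small-sample factor; they
are reported separately, not asserted equal.

## Problem sizes and tolerances

Monte-Carlo checks in the test suite use 500 zero-contrast slices for
null calibration and 50 seeds per condition for the
contrast/SNR-monotonicity sweeps — sizes at which the binomial/mean
standard errors are an order of magnitude below the asserted margins.
Determinism is asserted bitwise. Numerical tolerances: OLS betas match
the normal-equations oracle to 1e−8; agreement statistics match
hand-computed oracles to 1e−10; the simulator's rendered contrast is
accurate to ±0.002 (anti-aliasing) and measured SNR to ±10 %.

## Known limitations

- The ±8° search window bounds the recoverable rotation; beyond it the
  outer (small-spoke) holes are missed first.
- The AR(1) residual model is a first-order approximation to the true
  interpolation-induced correlation; it slightly over-corrects at very
  high SNR (conservative).
- Slice-8 spokes 8–10 at SNR ≈ 300 sit near the detection boundary by
  design of the insert; single-spoke score flicker between nearby
  acquisitions is expected there and mirrors human-rater variability.
- DICOM support targets standard single-frame series; enhanced
  multi-frame DICOM and non-axial reformats are out of scope.
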