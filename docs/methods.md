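# Methods

This note records the models implemented in `redoxscreen`, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical decisions that were genuinely open.

## Widefield optical redox ratio

Each field of view (FOV; one per gel) is an NAD(P)H / FAD autofluorescence
image pair. The analysis unit is the FOV, not the single cell: per-FOV
means are robust, cheap, and sufficient for screen-level comparisons.

Pipeline per FOV:

1. **Rolling-ball subtraction** on the NAD(P)H image. The background is
   the grayscale opening of the image with a disk structuring element
   (radius `rolling_ball_radius`), i.e. the classic rolling-ball
   construction: smooth structure wider than the element (vignetting,
   illumination gradients) goes into the background; compact bright
   features survive. The disk footprint is sequence-decomposed, which
   makes the opening fast at large radii. Properties guaranteed and
   tested: constant images map to zero, adding a constant leaves the
   output unchanged, and output ≤ input everywhere. The corrected image
   is used *only* for masking.
2. **Cell masking** by Otsu threshold on the corrected image (alternatives:
   fixed level, percentile), followed by removal of connected components
   smaller than `min_object_px`. Constant or foreground-free images raise
   a masking error rather than returning an empty mask silently.
   Externally generated masks/label images are accepted anywhere a mask is
   taken; the built-in thresholding is the fallback path, not a
   segmentation research tool.
3. **Cell intensity**: the arithmetic mean of the *raw* channel values
   under the mask, for both channels. The mask comes from the corrected
   NAD(P)H image but is always applied to raw data, so no morphology
   operation ever touches the measured intensities.
4. **Background intensity**: the mean over `n_background_rois` (default 3)
   square ROIs fully outside the mask after dilating it by
   `background_margin`. Selection is deterministic — grid candidates of
   size `roi_size`, lowest mask overlap first, ties broken by position —
   and the chosen boxes are recorded. Manual ROI coordinates override the
   automatic choice; that override is the faithful-reproduction path for
   datasets where background locations were picked by hand.
5. **Normalization and ORR**:
   `I_norm = I_cell / I_bg` per channel and
   `ORR = I_norm,NAD(P)H / (I_norm,NAD(P)H + I_norm,FAD)`.
   Each channel is divided by its own gel background, so any per-channel
   gain (exposure time, lamp drift, substrate autofluorescence) cancels
   identically — the testable core of the design. ORR is in (0, 1) for
   positive inputs, and swapping the channels maps ORR to 1 − ORR.

Saturated pixels (at a configured level) are excluded from all means and
flagged in the record's QC fields.

### Defaults

| knob | default | rationale |
|---|---|---|
| `rolling_ball_radius` | 50 px (24 px via `for_shape` on 192 px synthetic FOVs) | ≫ cell scale, ≪ field scale at 10×; scaled ~1/8 of field side for small synthetic images |
| threshold | Otsu | parameter-free, correct for bimodal cell/background histograms |
| `min_object_px` | 64 | removes noise specks without deleting small cells at 10× |
| `roi_size` / `n_background_rois` | 32 px / 3 | three background locations per gel; ROI comfortably larger than noise scale |
| `background_margin` | 8 px | keeps ROIs clear of mask fringes |

## TCSPC lifetime fitting

Time axis: 256 bins over one 12.5 ns repetition period (80 MHz source),
bin width 48.83 ps, bin centers at (k+0.5)·Δt; convolution lags use
t_m = m·Δt. The model per pixel is

```
expected[k] = A · Σ_j irf[j] · ( a1 e^{-t_{k-j}/tau1} + a2 e^{-t_{k-j}/tau2} ) + C
```

with a linear (non-circular) convolution truncated to the window. Both an
FFT route and a direct-summation route are provided; they agree to better
than 1e-12 relative and are cross-checked against a brute-force
double-loop oracle in the tests.

Fitting:

- **3×3 binning first** (each pixel's histogram summed over its 3×3
  neighborhood, edge pixels over the in-bounds subset), then only pixels
  with binned photon totals above the validity threshold (default 1000)
  are fit. Invalid pixels carry NaN in every map, never zeros.
- **Weights.** The objective is Σ_k w_k (data_k − model_k)². The default
  weighting is model-based (Pearson), w_k = 1/max(model_k, 1),
  re-evaluated as the optimizer moves. Data-based Neyman weights
  1/max(data_k, 1) are available (`weighting="neyman"`) but are *not* the
  default: at realistic photon budgets they over-weight
  downward-fluctuating low-count tail bins and bias both lifetimes low by
  ~7–11 %, which Pearson weighting reduces to a few percent. Both choices
  are weighted least squares; the default simply stays calibrated in the
  Poisson tail.
- **Free parameters** (5): tau1, tau2, a1 (a2 = 1 − a1 by construction),
  amplitude, offset C. Bounds: tau1 ∈ [50, 1500] ps, tau2 ∈ [1000, 8000]
  ps, a1 ∈ [0, 1], amplitude, offset ≥ 0 — the physiological NAD(P)H
  range, which also suppresses component swapping. After the fit,
  tau1 ≤ tau2 is enforced by swapping components and fractions.
- **Initialization**: tau1 = 500 ps, tau2 = 2500 ps, a1 = 0.5 (typical
  free/bound NAD(P)H values); offset = mean of up to 10 pre-rise bins;
  amplitude matched to the data peak.
- **Convergence**: scipy trust-region reflective least squares with
  ftol = xtol = gtol = 1e-10 and a function-evaluation cap; non-convergence
  flags the pixel invalid with a diagnostic message instead of raising.
- **χ²ᵣ** = weighted SS / (n_bins − 5). On correctly specified Poisson
  simulations the median sits near 0.9–1.0; the mild sub-unity offset
  comes from clamping the variance floor at 1 count in near-empty bins.
- **IRF alignment.** A coarse integer shift from the cross-correlation of
  the pooled (mask-summed) decay with the IRF is refined by a local χ²
  search over neighboring integer shifts, because the raw cross-correlation
  peak sits 1–3 bins late on decays (the decay skews mass rightward). The
  refined shift is applied to the IRF for all pixels of a cube.
- **tau_m = a1·tau1 + a2·tau2** is computed on every valid pixel and holds
  to machine precision by construction; aggregation over label images
  reports per-label means/medians over valid pixels only.

Out of scope by design: phasor analysis, triexponential models, FAD
lifetime fitting, vendor binary formats.

## Screen-level statistics

- The ScreenTable is a validated join of per-FOV records against the plate
  design; unknown keys are an error, missing cells are reported (not
  dropped), and row order never affects any output (tables are canonically
  sorted before summarizing, which also makes CSV outputs byte-identical
  under permutation).
- **Percent change** between days is computed on group means by default;
  averaging per-gel changes is provided as a switchable alternative
  (`method="per_gel"`), since "average change" is ambiguous between the
  two conventions.
- **Welch's t-test** is implemented from the closed form with
  Welch–Satterthwaite degrees of freedom; only the t CDF comes from scipy.
  Identical samples return t = 0, p = 1; zero variance with nonzero
  difference returns ±inf, p = 0. The implementation is cross-checked
  against scipy and an R `t.test` oracle in the tests.
- Omnibus procedures (repeated-measures/Welch ANOVA, Dunnett T3, Tukey)
  are deliberately not reimplemented; the ScreenTable CSV is the export
  path to a dedicated stats package.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions used throughout the tests:

- **IRF**: Gaussian, 240 ps FWHM, peak at bin 25. A real measured IRF
  (e.g. SHG from urea) has asymmetric tails; a parametric Gaussian is
  sufficient for synthesis and testing and is not a claim about any
  instrument.
- **Decay cubes**: per-pixel Poisson counts around
  photons_target · (IRF ⊛ normalized biexponential) + offset. Spatially
  homogeneous truth per cube; no scattered-light artifacts, no afterpulsing,
  no inter-period wrap-around of very long lifetimes.
- **Widefield pairs**: image = vignette · (bg + mask·(cell − bg)) + noise.
  Cells are random non-overlapping ellipses (the pipeline is
  morphology-agnostic); gel background defaults to 30 % of cell signal
  (configurable; "weak gel autofluorescence" is a qualitative statement,
  so the ratio is a knob, not a claim); vignetting is a radial cos⁴
  falloff of strength 0.15 shared by both channels; noise is Poisson shot
  noise plus Gaussian read noise (σ = 1 % of background, a CMOS camera
  model); intensities live in the 16-bit range with saturation clipped and
  flagged. Not emulated: chromatic registration error, focus drift,
  debris, photobleaching, per-channel vignette differences.
- **Plates**: one image pair per formulation × replicate × day; per-FOV
  true ORR = group trajectory value + Gaussian replicate jitter
  (σ = 0.01). Default group trajectories rise from day 6 to a day-10 peak,
  fall by day 16 and keep declining to day 100; the high-efficiency group
  starts higher and declines faster (−8.15 % vs −5.09 % from day 6 to 30).
  Cell geometries that leave fewer than three background ROIs are redrawn
  from the same seeded stream, keeping plates pure functions of their
  seed. Target ORR values are realized by fixing the FAD contrast
  (cell/bg = 10/3) and solving the NAD(P)H contrast from the ORR formula.

Because both channels share one vignette field, ORR recovery is exactly
vignette-invariant in the noiseless limit; passing tests therefore
demonstrate correct normalization arithmetic and masking, not robustness
to channel-dependent shading — which real optics can produce and which
would require a flat-field calibration outside this package's scope.

### Problem sizes

Simulated studies are sized to run comfortably on one CPU: decay-recovery
studies use a 32×32×256 cube (1024 fits); plate studies use 192×192 px
FOVs (rolling-ball radius 24, ROI size 24 via `WidefieldConfig.for_shape`)
with 12 formulations × 3 replicates × 4 days, and 20 independent seeds for
sign-pattern rates. These sizes are the package's own defaults for its
verification studies; all generators accept larger geometries.

## Known limitations

- Pearson-weighted least squares is still an approximation to Poisson
  maximum likelihood; a few-percent lifetime bias remains at ~1000
  photons and shrinks with photon count.
- The background-ROI automation assumes some cell-free area exists; fields
  with near-confluent coverage require manual ROIs.
- Rolling-ball correction assumes background structure is wider than the
  ball and cells are narrower; large cell clusters comparable to the ball
  radius will leak into the background estimate.
- The Welch test operates on per-FOV values and ignores the gel/replicate
  hierarchy; no mixed-effects modeling is attempted.
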