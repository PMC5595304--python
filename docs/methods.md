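# Methods

## Signal model and relaxometry

Each pixel of a multi-gradient-echo (MGE) magnitude stack is modeled as a
mono-exponential decay, `S(TE) = S0 · exp(−TE / T2*)`, with T2\* in ms and
the relaxation rate `R2* = 1000 / T2*` in s⁻¹. The emulated acquisition is
16 echoes at a 3.0 ms inter-echo spacing (TE = 3.0 … 48.0 ms) with 0.1 mm ×
0.1 mm in-plane pixels (0.01 mm²); both are configurable.

Fitting is nonlinear least squares on the exponential model, initialised by
log-linear regression of `ln S` on TE. When the log-linear solution already
reproduces the data to machine precision (noiseless input) it is returned
directly; otherwise `scipy.optimize.curve_fit` refines it with bounds
`S0 ≥ 0`, `0 < T2* ≤ T2MAX`. Choices that matter:

- **Noise floor** (`noise_floor`, signal units, default 0): echoes with
  magnitude at or below the floor are excluded before fitting. Magnitude
  MRI noise is Rician, which biases the tail of the decay upward; a floor
  of about 2× the background sigma (estimable from a signal-free region via
  the Rayleigh mean, `estimate_noise_sigma`) removes most of that bias. We
  fit magnitude data directly rather than using a Rician likelihood — the
  standard practice this package mirrors — and document the residual
  low-SNR bias as a known limitation.
- **Validity rule**: a pixel needs at least 4 usable echoes
  (`min_echoes=4`); fewer, or a degenerate fit, marks the pixel invalid
  rather than raising. The rule can be relaxed to 2, where the two-point
  closed form `T2* = ΔTE / ln(S1/S2)` applies.
- **T2MAX = 1000 ms**: non-decaying pixels (log-linear slope ≥ 0) are
  reported at the cap with flag `no_decay`, so R2\* ≈ 1 s⁻¹ ≈ 0 instead of
  an infinity.
- The inter-scan time of such protocols (~3 s) makes T1 weighting small; S0
  saturation is not modeled.

## Iron calibration

ROI mean R2\* per vial (one point per concentration) is regressed on known
iron(III) concentration by ordinary least squares, `R2* = a·c + b`, with
95 % confidence intervals from the t distribution on n−2 degrees of
freedom. At least 3 distinct concentrations are required and the fitted
slope must be positive (iron increases the relaxation rate). The inverse
map `c = (R2* − b)/a` is applied per valid pixel and **clipped** to the
calibrated range (default 0–0.3 mg g⁻¹, the working range of aqueous
iron(III) standards at 7 T) rather than masked, so iron maps stay dense.
For aqueous standards mg g⁻¹ and μg mL⁻¹ are treated as interchangeable
(density ≈ 1 g mL⁻¹). Calibrations are valid only for the acquisition they
were measured on; no field-strength transfer is attempted.

## Hot-spot clusters and statistics

Iron maps are stratified into a closed concentration band — the high-iron
band is [0.15, 0.3] mg g⁻¹, inclusive at both ends — and hot-spot clusters
are the connected components of the band mask. Defaults: 8-connectivity
(common particle-analysis practice) and `min_pixels = 1`; both are
arguments. Cluster areas are `pixel_count × pixel_area` (mm²); counts are
reported per image, with any per-animal or per-slice aggregation left to
the caller. Group comparisons are two-tailed throughout: unpaired
pooled-variance t, or Mann-Whitney with an exact p-value when
`min(n1, n2) ≤ 8` and the data are tie-free and the tie-corrected normal
approximation otherwise. Degenerate t inputs (zero pooled variance) return
p = 1 for equal means and p = 0 with a `zero_variance` flag otherwise.

## Histology and resolution matching

Stain-positive pixels are segmented by per-stain hue/saturation box rules
in HSV space (Prussian blue ≈ hue 180–280°, DAB ≈ 10–50°, fluorescence
≈ 90–160°; neutral-red counterstain wraps 320–20°). The defaults are tuned
on the synthetic slides, where planted truth is exact; real slides will
need per-batch adjustment through the exposed `StainRule` config. Objects
with area ≤ 20 μm² are removed (strict `>` keeps larger), separating single
HLMs and deposits from sub-cellular debris.

Resolution matching reduces the binary mask 1:100 by block averaging:
`values[i,j]` is the positive fraction of each 100×100 px tile, so at the
default 1 μm/px slide scale one reduced pixel equals one 0.1 mm MRI pixel
(the scale factor is recomputed from slide metadata when it differs).
Bilinear resampling onto the reduced grid is the identity once tiles are
block-aligned, so the block mean is the entire operation; trailing partial
tiles are zero-padded so the reduced map covers the full slide. The reduced
map is binarized at `values > 0` by default — the most inclusive rule, so
any positive mass forms a cluster — and labeled with the same
connected-component machinery as the MRI maps. Cells are counted per
cluster by assigning each full-resolution object to the cluster footprint
containing its centroid (exactly one, so totals are conserved).

Lesion surveys threshold the counterstain, fill holes (stained deposits
punch holes in the counterstain), and drop objects below 500 μm²
(configurable). Touching lesions merge — a documented limitation; no
watershed splitting is attempted. The survey reports per-lesion area, HLM
count, cluster areas, cells per cluster, and an iron-positive flag
(HLM count > 0); the summary percentage is `floor(100 · positive/total)`,
the floor convention implied by printed ratios such as 42/169 → 24 % and
86/105 → 81 %, and is undefined (None) for zero lesions.

## Synthetic data

Phantoms are hard disks of uniform T2\* on a uniform background (later
deposits win on overlap; no partial-volume blur, since no point-spread
model is assumed), with `S(TE)` evaluated exactly and noise added as:
Rician (default — magnitude of complex Gaussian noise, each channel sd
`noise_sigma`), plain Gaussian, or none (for oracle tests). Slides render
flat-colour cell disks of the planted area over counterstained lesion disks
on white, so detection ground truth is exact to the pixel. All randomness
flows from one integer seed per call; identical spec + seed is
bit-identical. The image SNR of real acquisitions is not prescribed
anywhere, so `noise_sigma` is a configuration choice; tests use 1 % of S0.

What the generators do **not** emulate — and therefore what passing tests
cannot certify on real data: lung air–tissue susceptibility artifacts,
motion and respiratory gating residue, coil inhomogeneity, stain texture
and colour variability, overlapping or densely packed cells, and
partial-volume effects at deposit edges.

## Problem sizes and determinism

The test suite and the acceptance script use 64×64 phantoms, 4-vial
calibration series (16–36 pixels per vial ROI, 100 noisy repeats for CI
coverage), 50 random masks per connectivity for the labeling oracle, 20
seeded 512×512 slides for cell-count conservation, and full enumeration of
all 3418 tie-free Mann-Whitney rank layouts with n1, n2 ≤ 6 — sizes chosen
so the full suite completes in a few minutes while keeping every check
statistically meaningful. Pipeline runs are deterministic given (config,
inputs, seed); CSV output uses fixed column order and 6-significant-digit
floats so reruns are byte-identical.

## Known limitations

- Magnitude-domain fitting underestimates T2\* at low SNR (Rician floor);
  mitigated, not removed, by the noise floor.
- Clipping (not masking) the iron map means out-of-range pixels silently
  saturate at the band edges.
- 2D only: no multi-slice cluster merging.
- Colour rules assume well-separated stain hues; no colour deconvolution.
- Cell identity is one connected stain-positive object; touching cells
  count as one.
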