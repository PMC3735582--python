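# Methods

This note records the models, parameter choices and numerical decisions
behind each stage, what the synthetic generators do and do not emulate, and
the known limitations.

## Penetration profiling (`diffusion`)

**Model.** A slice edge exposed to a constant tracer concentration behaves,
for a freely diffusing label, as a semi-infinite half-space:
`C(x,t) = C0·erfc(x/(2√(Dt)))` with effective diffusivity `D` (mm²/h).
The analysis does not fit `D`; it normalizes and averages, which is the
operation of interest. Distance normalization divides the depth axis by
`√t`, under which free-diffusion profiles are exactly self-similar;
amplitude normalization divides each curve by its edge value, estimated by
an ordinary least-squares cubic fit over a near-edge window, because the
sample at `x = 0` alone is noisy.

**Parameters.** Cubic-fit window: first 25% of the profile depth (at least
4 samples). A narrower window tracks curvature better but amplifies noise;
25% keeps the origin-estimate error under 3% at 2% noise on 200-sample
erfc profiles. Confidence band: pointwise Student-t 90% interval of the
mean across profiles; measured coverage of the true curve is 89.9% over
500 simulated ensembles of 20 profiles.

**Numerical decisions.** Profiles of different lengths are averaged on the
union of their distance grids clipped to the shortest profile, with linear
interpolation — no extrapolation ever occurs. Amplitude normalization is
exactly idempotent (a linear fit of scaled data is the scaled fit).
Amplitude normalization is applied after distance scaling; the order does
not matter mathematically (the distance axis rescaling leaves the fitted
origin value unchanged up to the window selection) but is fixed for
reproducibility. A fitted edge amplitude ≤ 0 raises a degenerate-profile
error rather than silently flipping the curve.

**Profile extraction.** Edge-normal lines are sampled at evenly spaced
arclength positions along the boundary polyline, with bilinear
interpolation at pixel-size spacing. Normals are oriented toward the
polyline centroid, which is the tissue interior for the convex-ish
sections this targets; strongly concave boundaries would need an explicit
interior point. A line leaving the image is truncated and flagged, not an
error. When no polyline is supplied the boundary is derived by Otsu
thresholding of a lightly smoothed image and the longest contour of the
largest connected component.

## Channel corrections (`corrections`)

**Bias (non-uniformity) field.** Modeled as a smooth multiplicative field,
estimated by least squares on log intensity with a separable polynomial
basis (order 3 per axis, 16 coefficients in 2D), exponentiated and
normalized to mean 1. This is a deliberate low-order surrogate for full
histogram-sharpening (N3-style) bias correction: the fields it targets are
smooth and low-order and the correction precedes display, so the heavier
machinery buys nothing here. Quadratic test fields are recovered to 0.23%
and re-estimation after correction leaves <1e-12 residual (the fit is
linear in log space, so correction exactly removes what was fitted).
Non-positive intensities are refused with a message instructing offset
handling, rather than being masked silently.

**Background (bleed-through) subtraction.** The stain channel is modeled as
`stain = signal + α·auto + noise` on background pixels. α is the slope of
an OLS regression of stain on auto (intercept included, slope returned)
restricted to background, made robust in two layers: pixels above the 95th
percentile of the stain are excluded up front, and up to 5 rounds of
trimming drop pixels whose residual exceeds 3 SD, so bright stained
foreground cannot lever the slope. On phantoms with ~10% stained
foreground the estimate lands within 0.5% of the generating α = 0.7.
Subtraction clips at zero and reports the clipped fraction — with a
zero-mean-noise background roughly half the background pixels clip, which
is informative, not an error.

**Punctate (hot-pixel) filter.** High-pass = image minus a 3×3 median
filter whose window *excludes the center pixel*. Two reasons: (i) the
residual of a pixel is then measured purely against its neighbors, so
subtracting the high-pass at a flagged pixel restores it exactly to the
neighborhood median; (ii) with the center included, the median correlates
with the pixel itself and the residual's tails become heavy relative to
its robust scale — measured false-positive rates at a 5-SD threshold were
~1e-4 per pixel versus ~3e-7 with the center excluded. The z-score divides
the high-pass by a local robust SD, 1.4826 × the median absolute high-pass
over a 15×15 window; a median-based scale is used so that a spike cannot
inflate its own denominator (one pixel cannot move a 225-sample median).
Zero-scale regions are floored at 1e-3 of the global robust SD. Only
positive excursions are flagged (the artifacts are bright), and flagged
8-connected components larger than 2 pixels are dropped as structure.
Defaults: hp_size 3, sd_window 15, threshold 5 SD. The filter is exactly
scale-equivariant, and pixels outside the mask are untouched bit for bit.

## Cell detection (`detect`)

Gaussian blur at the expected spot scale, then candidate pixels must pass
both an intensity threshold (absolute or quantile) and a local rank filter
(≥ the 99th percentile of a disk neighborhood, radius 5 px by default);
8-connected candidate clusters each become one cell at the unweighted mean
pixel location. Border-touching clusters are kept and flagged. On
300-spot phantoms with 6σ spot separation and 10% noise, recall and
precision are 100% with 0.40 px mean localization error. The known failure
mode is physical, not algorithmic: two cells closer than roughly the blur
scale merge into one detection, which undercounts crowded fields — visible
in the density-mapping example and in real dense tissue alike.

## Density mapping (`density`)

At each node of a coarse grid (default spacing 25× the source pixel size)
the k = 8 nearest cells give mean squared distance `mean(d²)`; reading
`π·mean(d²)` as a disk shared by the k cells gives per-cell area
`π·mean(d²)/k` and density `λ̂ = k/(π·mean(d²))`. The alternative reading
(`π·mean(d²)` is the per-cell area, differing by the constant factor k) is
selectable with `per_cell_area=False`; the ambiguity is inherent in the
verbal definition and documented rather than resolved.

**Finite-k bias.** For a homogeneous Poisson process, `π·λ·dᵢ²` is a sum of
i unit exponentials, so `λ̂/λ` is parameter-free with median ≈ 1.885 and
mean ≈ 2.10 at k = 8 (`knn_bias_factor` computes either). The raw
estimator therefore *overestimates* homogeneous density by ~1.9×; it is
kept raw by default because the display convention (30–1200 cells/mm²
gray ramp) is defined on the raw scale, and `bias_correction=True` divides
the factor out when calibrated values are wanted. Comparisons between two
maps should use ratios of region means, not means of pointwise ratios —
the latter are Jensen-biased upward by ~18% at k = 8.

**Determinism and edges.** Neighbor queries use a k-d tree with exact
distances; nodes whose k-th neighbor lies beyond the region boundary are
flagged `edge_biased` but still reported; nodes outside a supplied tissue
mask are missing (NaN) and render in a sentinel color (magenta) against
the linear 30→black / 1200→white gray ramp.

## Tomography plumbing (`opt_sim`)

Parallel-beam geometry (a good approximation for telecentric OPT optics):
the forward projector is the discrete Radon transform, reconstruction is
ramp-filtered back-projection with Hann apodization by default (pure ramp
selectable), both via scikit-image. The module exists so the correction/
detection/density chain can be exercised on reconstructed images; it does
not model scatter, attenuation, focal depth or any vendor reconstruction.
Round-trip correlation at 360 views is 0.9997 on a smooth 128² phantom.
Numerical honesty notes: projections of a centered radial object are
grid-exact only at 90° multiples (≈7e-4 relative spread elsewhere — the
bilinear-warp interpolation floor), and above a few hundred views the
reconstruction error is interpolation-dominated, so 1200 views is not
measurably better than 360 at these grid sizes.

## Synthetic phantoms (`synthetic`)

**Composition.** `auto = auto_clean + noise`;
`stain = bias·clean_stain + α·auto + punctate + noise`, all returned with
ground truth. Defaults emulate the acquisition regime the pipeline
targets: 256² grid at 0.02 mm/px, background level 100, Gaussian noise
SD 5 (~5% of background), bleed-through α = 0.7, ±20% quadratic-ish bias
field, 50 single-pixel punctate artifacts of amplitude 1000 with ≥3 px
separation (the removal filter targets isolated pixels). Diffusion
fronts use D = 0.01 mm²/h with incubation times 5/10/24/48 h; the
binding-limited ("hindered") regime is modeled as retarded diffusion
(D/R, R = 25) saturating at a binding capacity, which yields the
observed phenomenology — a saturated band behind a sharp front advancing
as √t — without claiming the true binding kinetics. Cell patterns are
inhomogeneous Poisson (tile-wise Poisson counts, uniform placement within
tiles); rendered cells are isotropic Gaussian spots.

**Randomness.** One top-level seed feeds named substreams (geometry, noise,
punctate, points) via CRC32-keyed generator keys, so each component is
independently and exactly reproducible; all outputs are bit-identical
under a repeated seed.

**What passing tests do not show.** Real data have structured (non-Gaussian,
possibly signal-dependent) camera noise, anisotropic PSFs, imperfect
channel registration, autofluorescence that is not simply additive, cells
of varying size/brightness, and non-convex tissue boundaries. The phantoms
make none of these claims; green tests demonstrate that the procedures are
implemented correctly and calibrated under their stated models, not that
the models capture every property of acquired images.

## Pipeline and formats (`io`, `pipeline`, `cli`)

Coordinates are 0-based pixel-center, `x = col·pixel_size`,
`y = row·pixel_size`, in mm, everywhere including CSV. Images travel as
single-channel float32 TIFF with a JSON description tag (pixel size,
channel, incubation time); an explicit pixel size always overrides file
metadata, with a logged warning on conflict, and its absence in both
places is a hard error. The run configuration is one flat JSON document;
unknown keys anywhere are rejected before any computation. The provenance
record (canonical config hash, seed, library versions, per-stage
summaries, relative artifact paths) contains no timestamps, so identical
runs are byte-identical — verified file-by-file in the tests. Problem
sizes throughout (256² phantoms, 512² detection scenes, 100-seed Monte
Carlo batches, 500-ensemble coverage runs) were chosen as the smallest
scales at which the measured quantities are stable to well within their
tolerances.

## Known limitations

- The bias surrogate assumes a smooth low-order field; high-frequency
  shading would need proper histogram-sharpening correction.
- The background regression assumes channels are co-registered and the
  bleed-through is spatially constant.
- Detection treats each cluster as one cell; touching cells merge
  (no watershed splitting), biasing density downward in crowded regions.
- The raw kNN density estimator carries its ~1.9× finite-k factor by
  design; always state whether reported values are raw or bias-corrected.
- The tomography module is plumbing, not an optics model.
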