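# Methods

This note records the models the package implements, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical decisions taken where the design was genuinely open.

## Cluster segmentation

The segmentation combines an intensity mask and a multi-scale blob mask.

*Mask 1.* The channel is smoothed with a 3×3 averaging filter (reflect
padding). The background SD of the smoothed image is estimated robustly as
`σ = 1.4826 × MAD`; pixels strictly above `median + N₁·σ` are kept. The
strict inequality makes constant images yield empty masks (σ = 0 there).
If the MAD collapses to zero on a non-constant image (integer-quantized
backgrounds), the mean absolute deviation substitutes so the threshold does
not collapse onto the median.

*Mask 2.* The raw image is filtered with a bank of LoG filters. Responses
are sign-flipped so bright blobs give positive peaks — required for the
negative-response removal rule to mean dark features and over-blurred edges
— and scale-normalized by `h²` so the robust per-scale thresholds `N₂·σ_h`
are comparable across scales. The truncated discrete LoG kernel has a tiny
nonzero sum; the filter is applied to the median-subtracted image so uniform
regions give exactly zero. A pixel passes if its response exceeds `N₂·σ_h`
at any scale and is removed if its largest negative response across scales
beats its largest positive one.

*Quantification.* Final mask = Mask 1 ∩ Mask 2 (∩ ROI if given). Background
is the median intensity outside the final mask, subtracted from the whole
image; pixels outside the mask are zeroed; negative values inside the mask
are clipped to 0 (keeps totals and overlap fractions non-negative).
Connected components (8-connectivity) of at least `min_cluster_px` pixels
become clusters; centroids are geometric (pixel-mean), areas are pixel
counts × pixel area.

### Segmentation parameters and why

- **Threshold multipliers.** The per-channel pairs used in the source
  signaling experiments ship as `CHANNEL_DEFAULTS` (Mask 1 / Mask 2: pCD79
  2/3, pSyk 2/5, pCD19 3/4). The generic default — used for the bright,
  high-contrast antigen channel — is the stricter (3, 4) pair. With
  `N₁ = 2`, the deterministic overlap of two bright diffraction-limited
  spots at six spot-sigmas separation already exceeds the Mask-1 threshold,
  so adjacent microclusters would merge regardless of noise; (3, 4) keeps
  spots at that separation resolvable while still capturing ≥ 90% of each
  spot's integral.
- **LoG width bank.** Default `h ∈ {1, 2, 4}` px: the diffraction-limited
  spot scale (σ ≈ 2 px at 0.1 µm pixels) bracketed by half and double. A
  width far above the feature scale (e.g. 8 px) responds to a close spot
  pair as a single blob and bridges the mask between them, merging
  well-separated spots; widths up to twice the spot scale instead place a
  negative ring between the spots that breaks such bridges.
- **Minimum cluster size.** Default 9 px (a 3×3 PSF core): no
  diffraction-limited spot resolves to fewer pixels, while thresholded noise
  clumps — which pass both masks a few times per 128² frame and are almost
  always ≤ 8 px — are discarded.
- **Border handling.** Reflect padding for both the mean and LoG filters.

Limitations: the threshold-contour truncation of a Gaussian spot loses mass
in the tails; for a spot at 15× the noise SD about 5–9% of the true integral
falls below threshold, so recovered totals are biased slightly low. No
flat-field correction, drift registration, or deconvolution is attempted.

## Synapse metrics

- Synapse centre = intensity-weighted centroid of all clustered antigen
  (the centre of mass of the antigen fluorescence); the per-frame mean
  cluster distance is an unweighted mean over clusters, and is normalized
  per cell to its maximum over the video (all-zero series stay zero).
- cSMAC call: strictly more than 90% of the clustered antigen intensity in
  at most 2 clusters; both the threshold and the cap are configuration
  values.
- `clusters_to_quantile` returns the smallest k whose k largest fractions
  reach the quantile (tolerance 1e-12 against floating-point accumulation).
- Cell footprint: Otsu threshold on the F-actin channel, largest connected
  component, hole filling. Constant (blank) images return an empty mask.
  This is an automated stand-in for what is often done by hand-drawn edges;
  it assumes a single dominant cell in the field.
- Kymographs: bilinear sampling every pixel along the segment, averaging
  `width_px` parallel lines; mean cluster distances, areas and times carry
  µm/µm²/s units throughout.

## Colocalization

The masked Manders coefficient M is the fraction of background-subtracted,
negative-clipped signal intensity inside its own segmentation mask that also
falls inside the reference mask. Clipping guarantees M ∈ [0, 1]; cells with
empty signal masks or non-positive clustered antigen are reported as errors
(excluded), never as zeros. Only the signal→reference direction is computed;
Pearson/Costes variants are out of scope.

## Single-particle diffusion

The observation model is 2-D isotropic Brownian motion (diffusion
coefficient D) observed at interval Δt with static Gaussian localization
error σ per axis and motion blur from a finite exposure, parameterized by
the blur coefficient R ∈ [0, ¼]. Displacements are stationary Gaussian with

    Var(Δ)        = 2DΔt + 2σ² − 4RDΔt
    Cov(Δₙ, Δₙ₊₁) = 2RDΔt − σ²

- **CVE**: closed-form inversion of the two moment equations; negative
  estimates are clipped to zero and flagged. Used standalone and as the MLE
  starting point.
- **MLE**: exact Gaussian likelihood of the x and y displacement sequences
  under the tridiagonal Toeplitz covariance, evaluated via banded Cholesky
  factorization (O(n) per evaluation), maximized over D ∈ [0, 10] µm²/s and
  σ ∈ [0, 0.5] µm with L-BFGS-B. The covariance is positive definite for
  all D, σ ≥ 0 when R ≤ ¼. Tracks with fewer than 10 displacements are
  reported as unestimated rather than silently dropped. Isotropy is
  assumed; drift and anomalous diffusion are not modelled.
- **R default 1/6** — continuous exposure over the full frame interval; the
  camera exposure fraction is configurable.
- **Confinement diameter** is the maximum pairwise distance within the
  track (computed via the convex hull for very long tracks). The
  alternative reading — maximum displacement from the first position — is
  not used; the pairwise definition is rotation/translation invariant and
  matches "diameter of maximum displacement".

## Statistics

- Mann–Whitney U: exact enumeration when `n_a·n_b ≤ 400` and no ties,
  otherwise the normal approximation with midrank tie and continuity
  corrections. Two-sided throughout.
- Two-sample KS: asymptotic two-sided p.
- ROUT at Q: the published method is defined for nonlinear regression; for
  per-cell scalar measurements this package uses the univariate
  specialization: robust centre = median, RSDR = 68.27th percentile of
  |residuals| × n/(n−1), and an outermost-first Benjamini–Hochberg-style
  schedule on t-ratios (df = n−1) at rate Q; everything at least as extreme
  as the outermost accepted value is flagged. All-identical samples flag
  nothing; a zero RSDR on non-identical data falls back to the mean
  absolute deviation.
- Activation index: geometric mean of the stimulated sample minus geometric
  mean of the control, optionally as percent of the control response.
  The paired t-test is a thin wrapper provided for matched designs.

## Synthetic data: what it emulates, and what it does not

The generators define the conditions under which the pipeline is validated.

- **Scenes**: isotropic Gaussian spots (the diffraction-limited PSF
  approximation) on a constant background with additive Gaussian read noise
  (optional Poisson shot noise). Defaults: 0.1 µm pixels, spot σ 0.2 µm,
  background 100 AU, noise SD 5 AU, spot amplitudes 75–125 AU (15–25× the
  noise SD — bright, high-SNR microclusters), spots placed in a 1–4.5 µm
  annulus with ≥ 1.2 µm (six spot-sigma) pairwise separation. Ground truth
  records each spot's analytic centroid and integral `A·2π(σ/px)²`.
- **Coalescence**: each frame moves every spot toward the synapse centre by
  `drift·Δt` (clamped at the centre); spots within the merge distance fuse
  into one whose integral is conserved, centre is the intensity-weighted
  mean, and width the intensity-weighted RMS of the parents. Defaults:
  2.5 µm/min drift (the actin retrograde-flow speed), 12-s frames, 51
  frames (10 min), 0.5 µm merge distance. `frozen=True` disables motion —
  the negative control.
- **Two-channel overlap**: two flat-topped square features carrying exactly
  `inside_fraction` and `1 − inside_fraction` of a fixed total, one inside
  the reference mask, one disjoint. Sharp edges make the noise-free overlap
  fraction exact, so the construction is its own oracle.
- **Trajectories**: Brownian sub-steps; the reported frame position is the
  mean of m sub-positions sampled at offsets `i·(fΔt/m)` within the
  exposure window plus Gaussian localization error. This discrete averaging
  has effective blur coefficient `R = f·(m² − 1)/(6m²)` (→ f/6 as m → ∞);
  with the default m = 10 and full-frame exposure, R = 0.165, which the
  1/6-based estimator absorbs with < 1% bias. A reflecting circular
  boundary (radial folding at the wall) implements confinement. Defaults
  match the tracking conditions: 330 frames at 33 Hz (10 s),
  D = 0.05 µm²/s, σ = 0.03 µm.

Not emulated: spatially varying background and vignetting, pixelation of
the PSF beyond sampling, camera gain/EM noise statistics, z-drift, spot
blinking and photobleaching, APC-side fluorescence, receptor
immobilization/state switching, and tracking/linking errors (trajectories
arrive pre-linked). Passing tests therefore demonstrate correctness of the
measurement chain under the stated model, not robustness to every artifact
of real recordings.

## Problem sizes and determinism

Validation uses 128×128 px scenes (a 12.8 µm field holding a 10 µm
synapse), 50 seeded scenes for recovery, 20 + 20 cells × 51 frames for
coalescence discrimination, 200 tracks per condition for SPT recovery, and
1000 null simulations for test calibration. Every generator draws all its
randomness from a single seeded generator, and the pipeline records the
configuration hash and input/output SHA-256 digests in its manifest; two
runs with the same configuration and seed are byte-identical.
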