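# synaptiq

Quantification of B-cell immune-synapse imaging experiments: robust
segmentation of BCR–antigen microclusters in fluorescence images, per-cell
coalescence and cSMAC metrics, signaling-to-antigen colocalization, and
localization-noise/motion-blur-corrected diffusion estimation for
single-particle tracks — together with ground-truthed synthetic data
generators that make every stage testable without raw microscopy data.

## Who this is for

When a B cell contacts an antigen-presenting cell, antigen-engaged B-cell
receptors (BCRs) gather into submicron microclusters that move centripetally
and coalesce into a central supramolecular activation cluster (cSMAC).
Quantifying that process from time-lapse fluorescence microscopy — and
relating it to receptor mobility measured by single-particle tracking (SPT) —
requires a chain of bespoke measurements that this package implements as a
tested, reusable library with a thin CLI.

## The methods at its core

**Two-mask cluster segmentation.** An image `I` is smoothed with a 3×3
averaging filter; the background SD is estimated robustly as
`σ = 1.4826 × MAD(F₃ₓ₃(I))`. Mask 1 keeps pixels above `median + N·σ` of the
smoothed image. Mask 2 filters the raw image with a bank of
Laplacian-of-Gaussian (LoG) filters of widths `h`, estimates a per-scale
`σ_h = 1.4826 × MAD(LoG_h(I))`, keeps pixels whose bright-blob-positive
response exceeds `N·σ_h` at any scale, and removes pixels whose strongest
negative response beats their strongest positive one. The final mask is
`Mask 1 ∩ Mask 2`; background (median outside the mask) is subtracted, and
connected components become clusters with summed intensities.

**Synapse metrics.** Per frame: cluster count, mean cluster area, the
descending per-cluster intensity fractions, the number of clusters holding
90% of the antigen fluorescence, the mean cluster distance to the
intensity-weighted synapse centre (normalized per cell to its own maximum),
and the cSMAC call (>90% of clustered antigen in ≤2 clusters). Plus cell
footprints/searched area from an F-actin channel and kymographs.

**Colocalization.** Masked Manders coefficient: the intensity-weighted
fraction of background-subtracted clustered signal (e.g. pCD19) lying inside
the reference (BCR–antigen) mask, and the signaling-per-antigen ratio.

**SPT diffusion.** Per-axis displacements of a 2-D Brownian track observed
with static localization error `σ_loc` and camera blur `R` are stationary
Gaussian with tridiagonal covariance `Var(Δ) = 2DΔt + 2σ² − 4RDΔt`,
`Cov(Δₙ,Δₙ₊₁) = 2RDΔt − σ²`. The package provides the closed-form
covariance-based estimator and an exact MLE via banded Cholesky
factorization, plus confinement diameters (maximum pairwise displacement)
and cumulative-frequency summaries.

**Statistics.** Mann–Whitney U, two-sample Kolmogorov–Smirnov, a univariate
ROUT (FDR-controlled outlier flagging at Q = 1%), and geometric-mean
activation indices.

## Worked example

```python
import numpy as np
from synaptiq import (CoalescenceSpec, segment_clusters, simulate_coalescence,
                      summarize_time_series)
from synaptiq.synthetic import default_synapse_scene

scene = default_synapse_scene(np.random.default_rng(0), n_spots=10)
images, truth = simulate_coalescence(CoalescenceSpec(scene=scene))
series = summarize_time_series([segment_clusters(img) for img in images])
first, last = series.frames[0], series.frames[-1]
print(f"clusters {first.n_clusters} -> {last.n_clusters}")
print(f"largest fraction {first.largest_fraction:.3f} -> {last.largest_fraction:.3f}")
print(f"normalized distance -> {series.normalized_distance[-1]:.3f}")
print(f"cSMAC at final frame: {last.is_csmac}")
```

prints

```
clusters 10 -> 1
largest fraction 0.118 -> 1.000
normalized distance -> 0.000
cSMAC at final frame: True
```

Ten simulated microclusters drift centripetally at 2.5 µm/min and merge: by
10 min all antigen sits in one central cluster (fraction 1.000, normalized
distance 0), so the cell is called cSMAC-positive. With `frozen=True` the
same cell keeps 10 clusters and is never called a cSMAC.

The same workflow is available from the shell:

```sh
synaptiq run --seed 1 --out runs/demo
```

which writes cluster tables, per-frame metrics, overlap results, per-track
diffusion estimates, a statistics table, and a manifest with the config hash
and the SHA-256 of every input and output.

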