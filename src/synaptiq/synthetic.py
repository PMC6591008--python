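"""Ground-truthed synthetic data for every analysis stage.

Emulates the statistical structure the pipeline assumes:

* single frames of diffraction-limited Gaussian spots on a noisy background
  (the imaged antigen channel of an immune synapse);
* time series in which spots drift centripetally at a fixed speed and merge
  when they meet, so microcluster coalescence into a central cluster (cSMAC)
  can be produced or suppressed at will;
* paired signal/reference channels with an exactly controlled fraction of
  signal intensity inside the reference mask (colocalization oracle);
* 2-D Brownian particle trajectories with exposure blur (discrete sub-step
  averaging) and Gaussian localization error, optionally confined by a
  reflecting circular boundary.

All generators are deterministic given their spec's ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .segmentation import Cluster, ClusterSet, IntensityImage

__all__ = [
    "GaussianSpot",
    "SceneSpec",
    "CoalescenceSpec",
    "TrajectorySpec",
    "Trajectory",
    "simulate_scene",
    "simulate_coalescence",
    "simulate_two_channel",
    "simulate_trajectory",
    "blur_coefficient",
    "default_synapse_scene",
]


@dataclass(frozen=True)
class GaussianSpot:
    """Isotropic Gaussian spot: centre (x, y) in µm, peak amplitude, width."""

    center_um: tuple[float, float]
    amplitude: float
    sigma_um: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not self.sigma_um > 0:
            raise ValueError("sigma_um must be positive")

    def integral(self, pixel_size_um: float) -> float:
        """Noise-free integrated intensity in pixel units, A·2π(σ/px)²."""
        s = self.sigma_um / pixel_size_um
        return self.amplitude * 2.0 * np.pi * s * s


@dataclass(frozen=True)
class SceneSpec:
    """One synthetic image: spots on a constant background plus noise."""

    image_shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.1
    spots: tuple[GaussianSpot, ...] = ()
    background_level: float = 100.0
    noise_sd: float = 5.0
    poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_shape) < 1:
            raise ValueError("image_shape must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "spots", tuple(self.spots))


@dataclass(frozen=True)
class CoalescenceSpec:
    """Time series in which spots drift toward a synapse centre and merge.

    Defaults emulate the imaging conditions of B cell-APC synapse videos:
    one frame every 12 s for ~10 min, centripetal drift at the actin
    retrograde-flow speed of ~2.5 µm/min.
    """

    scene: SceneSpec = field(default_factory=SceneSpec)
    n_frames: int = 51
    frame_interval_s: float = 12.0
    drift_speed_um_per_min: float = 2.5
    center_um: tuple[float, float] = (6.4, 6.4)
    merge_distance_um: float = 0.5
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.drift_speed_um_per_min < 0:
            raise ValueError("drift speed must be >= 0")
        if self.merge_distance_um < 0:
            raise ValueError("merge_distance_um must be >= 0")


@dataclass(frozen=True)
class TrajectorySpec:
    """2-D Brownian trajectory with exposure blur and localization error.

    Defaults match single-particle tracking at 33 Hz for 10 s with
    full-frame exposure; blur is simulated by averaging ``n_substeps``
    intra-frame positions, giving an effective blur coefficient
    ``R = exposure_fraction * (m² - 1) / (6 m²)`` (→ 1/6 as m → ∞).
    """

    d_um2_per_s: float = 0.05
    sigma_loc_um: float = 0.03
    n_frames: int = 330
    frame_interval_s: float = 1.0 / 33.0
    exposure_fraction: float = 1.0
    n_substeps: int = 10
    confinement_diameter_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_um2_per_s < 0 or self.sigma_loc_um < 0:
            raise ValueError("d and sigma_loc must be >= 0")
        if not (0 < self.exposure_fraction <= 1):
            raise ValueError("exposure_fraction must be in (0, 1]")
        if self.n_substeps < 1 or self.n_frames < 2:
            raise ValueError("n_substeps >= 1 and n_frames >= 2 required")
        if self.confinement_diameter_um is not None and self.confinement_diameter_um <= 0:
            raise ValueError("confinement_diameter_um must be positive")


@dataclass(frozen=True)
class Trajectory:
    """One particle's consecutive (x, y) positions at fixed frame interval."""

    track_id: int
    frame_interval_s: float
    positions_um: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise ValueError("positions must be an (n>=2, 2) array")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        object.__setattr__(self, "positions_um", pos)

    def __len__(self) -> int:
        return self.positions_um.shape[0]


def blur_coefficient(exposure_fraction: float = 1.0, n_substeps: int = 10) -> float:
    """Effective motion-blur coefficient of the discrete sub-step simulator.

    Averaging ``m`` positions sampled at offsets ``i * (f Δt / m)``,
    ``i = 0..m-1``, within each frame yields ``R = f (m² - 1) / (6 m²)``;
    the continuous full-frame limit is the textbook 1/6.
    """
    m = n_substeps
    return exposure_fraction * (m * m - 1) / (6.0 * m * m)


def _render_spots(spec: SceneSpec) -> np.ndarray:
    rows, cols = spec.image_shape
    y = np.arange(rows)[:, None] * spec.pixel_size_um
    x = np.arange(cols)[None, :] * spec.pixel_size_um
    img = np.zeros(spec.image_shape, dtype=float)
    for s in spec.spots:
        cx, cy = s.center_um
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        img += s.amplitude * np.exp(-r2 / (2.0 * s.sigma_um**2))
    return img


def _check_spots_inside(spec: SceneSpec) -> None:
    rows, cols = spec.image_shape
    xmax = (cols - 1) * spec.pixel_size_um
    ymax = (rows - 1) * spec.pixel_size_um
    bad = [
        s
        for s in spec.spots
        if not (0 <= s.center_um[0] <= xmax and 0 <= s.center_um[1] <= ymax)
    ]
    if bad:
        raise ValueError(f"spot centers outside the image: {bad}")


def _truth_cluster_set(spec: SceneSpec) -> ClusterSet:
    """Ground truth as a degenerate ClusterSet (analytic centroids/integrals,
    no pixel support)."""
    empty = np.empty(0, dtype=int)
    clusters = [
        Cluster(
            id=i,
            pixel_rows=empty,
            pixel_cols=empty,
            centroid_um=s.center_um,
            area_um2=2.0 * np.pi * s.sigma_um**2,
            total_intensity=s.integral(spec.pixel_size_um),
        )
        for i, s in enumerate(spec.spots)
    ]
    return ClusterSet(
        clusters, spec.background_level, None, spec.image_shape, spec.pixel_size_um
    )


def _add_noise(clean: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    img = clean
    if spec.poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img


def simulate_scene(spec: SceneSpec) -> tuple[IntensityImage, ClusterSet]:
    """Render one frame: background + Gaussian spots + noise, with truth.

    The ground-truth set records each spot's analytic centroid and noise-free
    integrated intensity ``amplitude · 2π (σ/px)²``.
    """
    _check_spots_inside(spec)
    rng = np.random.default_rng(spec.seed)
    clean = spec.background_level + _render_spots(spec)
    img = _add_noise(clean, spec, rng)
    image = IntensityImage(img, spec.pixel_size_um, channel_name="Ag")
    return image, _truth_cluster_set(spec)


def _merge_spots(spots: list[GaussianSpot], merge_distance: float, px: float) -> list[GaussianSpot]:
    """Iteratively merge closest pairs within ``merge_distance``.

    The merged spot conserves the integrated intensity; its centre is the
    intensity-weighted mean and its width the intensity-weighted RMS of the
    parents' widths.
    """
    spots = list(spots)
    while len(spots) > 1:
        centers = np.array([s.center_um for s in spots])
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] > merge_distance:
            break
        a, b = spots[i], spots[j]
        wa, wb = a.integral(px), b.integral(px)
        w = wa + wb
        center = (
            (wa * a.center_um[0] + wb * b.center_um[0]) / w,
            (wa * a.center_um[1] + wb * b.center_um[1]) / w,
        )
        sigma = float(np.sqrt((wa * a.sigma_um**2 + wb * b.sigma_um**2) / w))
        amplitude = w / (2.0 * np.pi * (sigma / px) ** 2)
        merged = GaussianSpot(center, amplitude, sigma)
        spots = [s for k, s in enumerate(spots) if k not in (i, j)] + [merged]
    return spots


def simulate_coalescence(
    spec: CoalescenceSpec,
) -> tuple[list[IntensityImage], list[ClusterSet]]:
    """Render a drift-and-merge time series with per-frame ground truth.

    Frame 0 is the initial scene; each subsequent frame moves every spot
    toward ``center_um`` by ``drift_speed · frame_interval`` (clamped at the
    centre) unless ``frozen``, then merges spots whose centres are within
    ``merge_distance_um``.  Total ground-truth integrated intensity is
    conserved across frames by construction.
    """
    _check_spots_inside(spec.scene)
    rng = np.random.default_rng(spec.scene.seed)
    px = spec.scene.pixel_size_um
    step_um = spec.drift_speed_um_per_min / 60.0 * spec.frame_interval_s
    cx, cy = spec.center_um

    spots = list(spec.scene.spots)
    images: list[IntensityImage] = []
    truths: list[ClusterSet] = []
    for frame in range(spec.n_frames):
        if frame > 0 and not spec.frozen:
            moved = []
            for s in spots:
                dx, dy = cx - s.center_um[0], cy - s.center_um[1]
                r = float(np.hypot(dx, dy))
                if r <= step_um or r == 0.0:
                    center = (cx, cy)
                else:
                    center = (
                        s.center_um[0] + dx / r * step_um,
                        s.center_um[1] + dy / r * step_um,
                    )
                moved.append(replace(s, center_um=center))
            spots = _merge_spots(moved, spec.merge_distance_um, px)
        frame_scene = replace(spec.scene, spots=tuple(spots))
        clean = frame_scene.background_level + _render_spots(frame_scene)
        img = _add_noise(clean, frame_scene, rng)
        images.append(
            IntensityImage(
                img, px, channel_name="Ag", time_s=frame * spec.frame_interval_s
            )
        )
        truths.append(_truth_cluster_set(frame_scene))
    return images, truths


def simulate_two_channel(
    spec: SceneSpec, inside_fraction: float, total_intensity: float = 50000.0
) -> tuple[IntensityImage, np.ndarray, dict]:
    """Signal channel + reference mask with a controlled overlap fraction.

    Places two flat-topped square features: one inside the reference mask
    carrying ``inside_fraction`` of the total background-subtracted signal,
    one disjoint from it carrying the remainder.  Sharp-edged (non-Gaussian)
    features make the noise-free overlap fraction exact, so the construction
    itself is the oracle for Manders-style overlap measurements.

    Returns
    -------
    (signal_image, reference_mask, truth)
        ``truth`` holds the exact ``signal_mask``, per-feature totals and the
        requested ``inside_fraction``.
    """
    if not (0.0 <= inside_fraction <= 1.0):
        raise ValueError("inside_fraction must be in [0, 1]")
    rows, cols = spec.image_shape
    size = max(4, min(rows, cols) // 8)
    rng = np.random.default_rng(spec.seed)

    r0 = rows // 2 - size // 2
    in_block = (slice(r0, r0 + size), slice(cols // 4 - size // 2, cols // 4 + size - size // 2))
    out_block = (
        slice(r0, r0 + size),
        slice(3 * cols // 4 - size // 2, 3 * cols // 4 + size - size // 2),
    )
    n_px = size * size
    signal = np.full(spec.image_shape, spec.background_level, dtype=float)
    signal[in_block] += inside_fraction * total_intensity / n_px
    signal[out_block] += (1.0 - inside_fraction) * total_intensity / n_px
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)

    reference = np.zeros(spec.image_shape, dtype=bool)
    reference[in_block] = True
    signal_mask = np.zeros(spec.image_shape, dtype=bool)
    if inside_fraction > 0:
        signal_mask[in_block] = True
    if inside_fraction < 1:
        signal_mask[out_block] = True

    truth = {
        "signal_mask": signal_mask,
        "inside_fraction": inside_fraction,
        "inside_total": inside_fraction * total_intensity,
        "outside_total": (1.0 - inside_fraction) * total_intensity,
        "total": total_intensity,
    }
    image = IntensityImage(signal, spec.pixel_size_um, channel_name="signal")
    return image, reference, truth


def simulate_trajectory(spec: TrajectorySpec) -> tuple[Trajectory, dict]:
    """Simulate one blurred, noisy 2-D Brownian track.

    Per frame, ``n_substeps`` intra-exposure positions are simulated at
    offsets ``i * (exposure_fraction Δt / m)`` and averaged; independent
    Gaussian localization error of SD ``sigma_loc_um`` per axis is added to
    the averaged position.  A reflecting circular boundary (folding at the
    wall) is applied at sub-step level when confinement is set.

    Returns the trajectory and the true parameters, including the effective
    blur coefficient of the discrete averaging.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_substeps
    dt = spec.frame_interval_s
    sub_dt = spec.exposure_fraction * dt / m
    gap_dt = dt - (m - 1) * sub_dt
    step_sd_sub = np.sqrt(2.0 * spec.d_um2_per_s * sub_dt)
    step_sd_gap = np.sqrt(2.0 * spec.d_um2_per_s * gap_dt)
    radius = (
        spec.confinement_diameter_um / 2.0
        if spec.confinement_diameter_um is not None
        else None
    )

    def reflect(p: np.ndarray) -> np.ndarray:
        if radius is None:
            return p
        r = float(np.hypot(*p))
        while r > radius:
            p = p * (2.0 * radius - r) / r
            r = abs(2.0 * radius - r)
        return p

    pos = np.zeros(2)
    reported = np.empty((spec.n_frames, 2))
    for frame in range(spec.n_frames):
        samples = np.empty((m, 2))
        samples[0] = pos
        for i in range(1, m):
            pos = reflect(pos + rng.normal(0.0, step_sd_sub, size=2))
            samples[i] = pos
        reported[frame] = samples.mean(axis=0)
        pos = reflect(pos + rng.normal(0.0, step_sd_gap, size=2))
    if spec.sigma_loc_um > 0:
        reported = reported + rng.normal(
            0.0, spec.sigma_loc_um, size=reported.shape
        )

    truth = {
        "d_um2_per_s": spec.d_um2_per_s,
        "sigma_loc_um": spec.sigma_loc_um,
        "r_effective": blur_coefficient(spec.exposure_fraction, m),
    }
    return Trajectory(0, dt, reported), truth


def default_synapse_scene(
    rng: np.random.Generator,
    n_spots: int = 10,
    center_um: tuple[float, float] = (6.4, 6.4),
    r_min_um: float = 1.0,
    r_max_um: float = 4.5,
    min_separation_um: float = 1.2,
    amplitude_range: tuple[float, float] = (75.0, 125.0),
    sigma_um: float = 0.2,
    **scene_kwargs,
) -> SceneSpec:
    """Random synapse-like scene: bright spots scattered in an annulus.

    Spot amplitudes default to 15–25× the default noise SD (5 AU) —
    high-SNR diffraction-limited microclusters — placed with a minimum
    pairwise separation so individual spots remain resolvable.
    """
    centers: list[tuple[float, float]] = []
    for _ in range(10000):
        if len(centers) == n_spots:
            break
        r = rng.uniform(r_min_um, r_max_um)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        cand = (center_um[0] + r * np.cos(theta), center_um[1] + r * np.sin(theta))
        if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) >= min_separation_um for c in centers):
            centers.append(cand)
    if len(centers) < n_spots:
        raise RuntimeError("could not place spots with the requested separation")
    spots = tuple(
        GaussianSpot(c, rng.uniform(*amplitude_range), sigma_um) for c in centers
    )
    return SceneSpec(
        spots=spots, seed=int(rng.integers(0, 2**31 - 1)), **scene_kwargs
    )
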