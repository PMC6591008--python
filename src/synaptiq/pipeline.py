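"""End-to-end runs: simulation → segmentation → metrics → coloc → SPT → stats.

A run consumes either user-supplied inputs (antigen/signal TIFF series,
tracks CSV) or, when none are given, a packaged synthetic demo (one
coalescing and one frozen synapse, a two-channel overlap pair, and a small
set of Brownian tracks).  Every run writes CSV tables, JSON summaries and a
machine-readable manifest (package version, config hash, SHA-256 of every
input and output) into the output directory.  Runs are deterministic given
the configuration seed.
"""

from __future__ import annotations

import hashlib
import logging
import shutil
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .io import (
    read_image_series,
    read_tracks,
    write_cluster_table,
    write_image_series,
    write_json,
    write_tracks,
)
from .coloc import overlap_result, signaling_per_ag
from .metrics import summarize_time_series
from .segmentation import segment_clusters, total_clustered_intensity
from .spt import BlurModel, confinement_diameter, cve_estimate, mle_estimate
from .stats import ks_two_sample, mann_whitney_u, rout_outliers
from .synthetic import (
    CoalescenceSpec,
    TrajectorySpec,
    default_synapse_scene,
    simulate_coalescence,
    simulate_trajectory,
    simulate_two_channel,
)

__all__ = ["run_pipeline", "simulate_demo_inputs"]

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_demo_inputs(out_dir: Path, config: RunConfig) -> dict[str, Path]:
    """Generate the packaged synthetic demo inputs into ``out_dir``."""
    rng = np.random.default_rng(config.seed)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, Path] = {}

    for name, frozen in (("coalescing", False), ("frozen", True)):
        scene = default_synapse_scene(rng, n_spots=8)
        spec = CoalescenceSpec(scene=scene, n_frames=21, frozen=frozen)
        images, _ = simulate_coalescence(spec)
        path = out_dir / f"ag_{name}.tif"
        write_image_series(path, images)
        inputs[f"ag_{name}_tiff"] = path

    scene = default_synapse_scene(rng, n_spots=4)
    signal, reference, _ = simulate_two_channel(
        replace(scene, noise_sd=2.0), inside_fraction=0.6
    )
    path = out_dir / "signal.tif"
    write_image_series(path, [signal])
    inputs["signal_tiff"] = path
    np.save(out_dir / "reference_mask.npy", reference)

    tracks = []
    for i in range(20):
        spec = TrajectorySpec(seed=int(rng.integers(0, 2**31 - 1)))
        traj, _ = simulate_trajectory(spec)
        tracks.append(replace(traj, track_id=i))
    path = out_dir / "tracks.csv"
    write_tracks(path, tracks)
    inputs["tracks_csv"] = path
    return inputs


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    inputs: dict[str, Path] | None = None,
    pixel_size_um: float | None = 0.1,
) -> Path:
    """Execute the full analysis and write all outputs plus a manifest.

    Parameters
    ----------
    config
        Validated run configuration.
    out_dir
        Output directory (created; partial outputs are removed on failure).
    inputs
        Mapping of input names to paths.  Recognized keys:
        ``ag_*_tiff`` (antigen series, segmented and summarized per cell),
        ``signal_tiff`` (signal channel for colocalization; requires a
        ``reference_mask.npy`` next to it or an ``ag_*_tiff`` final mask),
        ``tracks_csv`` (SPT trajectories).  ``None`` generates the synthetic
        demo inputs first.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out_dir, inputs, pixel_size_um)
    except Exception:
        shutil.rmtree(out_dir, ignore_errors=True)
        raise


def _run(
    config: RunConfig,
    out_dir: Path,
    inputs: dict[str, Path] | None,
    pixel_size_um: float | None,
) -> Path:
    ag_params = config.segmentation_params("Ag")
    if inputs is None:
        inputs = simulate_demo_inputs(out_dir / "inputs", config)
    warnings_count = 0
    outputs: list[Path] = []
    summary: dict = {}

    # --- segmentation + per-cell synapse metrics ---------------------------
    final_masks = {}
    for key, path in sorted(inputs.items()):
        if not key.startswith("ag_"):
            continue
        cell = key[3:].removesuffix("_tiff")
        images = read_image_series(path, pixel_size_um=pixel_size_um, channel_name="Ag")
        cluster_sets = [segment_clusters(img, ag_params) for img in images]
        final_masks[cell] = cluster_sets[-1].final_mask
        table_path = out_dir / f"clusters_{cell}.csv"
        write_cluster_table(table_path, cluster_sets)
        outputs.append(table_path)

        series = summarize_time_series(
            cluster_sets,
            times_s=[img.time_s for img in images],
            csmac_threshold=config.csmac_threshold,
            csmac_max_clusters=config.csmac_max_clusters,
        )
        rows = [
            {
                "frame": i,
                "n_clusters": f.n_clusters,
                "mean_cluster_area_um2": f.mean_cluster_area_um2,
                "total_ag_intensity": f.total_ag_intensity,
                "largest_fraction": f.largest_fraction,
                "top2_fraction": f.top2_fraction,
                "clusters_to_q90": f.clusters_to_q90,
                "mean_distance_um": f.mean_distance_um,
                "normalized_distance": series.normalized_distance[i],
                "is_csmac": f.is_csmac,
            }
            for i, f in enumerate(series.frames)
        ]
        metrics_path = out_dir / f"metrics_{cell}.csv"
        pd.DataFrame(rows).to_csv(metrics_path, index=False)
        outputs.append(metrics_path)
        summary[f"csmac_final_{cell}"] = bool(series.frames[-1].is_csmac)
        summary[f"total_ag_final_{cell}"] = total_clustered_intensity(
            cluster_sets[-1]
        )

    # --- colocalization ----------------------------------------------------
    if "signal_tiff" in inputs:
        signal = read_image_series(
            inputs["signal_tiff"], pixel_size_um=pixel_size_um, channel_name="signal"
        )[0]
        ref_path = Path(inputs["signal_tiff"]).parent / "reference_mask.npy"
        reference = (
            np.load(ref_path)
            if ref_path.exists()
            else next(iter(final_masks.values()))
        )
        signal_params = config.segmentation_params(
            "pCD79" if "pCD79" in config.channels else "Ag"
        )
        cs = segment_clusters(signal, signal_params)
        if cs.final_mask.any():
            res = overlap_result(signal, cs.final_mask, reference)
            coloc_row = {
                "signal_total": res.signal_total,
                "signal_in_reference": res.signal_in_reference,
                "manders_fraction": res.manders_fraction,
            }
            ag_total = summary.get("total_ag_final_coalescing")
            if ag_total:
                coloc_row["signal_per_ag"] = signaling_per_ag(
                    res.signal_total, ag_total
                )
            coloc_path = out_dir / "coloc.csv"
            pd.DataFrame([coloc_row]).to_csv(coloc_path, index=False)
            outputs.append(coloc_path)
            summary["manders_fraction"] = res.manders_fraction

    # --- SPT ---------------------------------------------------------------
    if "tracks_csv" in inputs:
        tracks = read_tracks(inputs["tracks_csv"], config.frame_interval_s)
        blur = BlurModel(config.blur_r)
        rows = []
        for t in tracks:
            row = {"track_id": t.track_id, "n": len(t)}
            if len(t) - 1 >= config.min_track_displacements:
                est = mle_estimate(
                    t, blur, config.d_max, config.sigma_max,
                    config.min_track_displacements,
                )
                row.update(
                    d_um2_per_s=est.d_um2_per_s,
                    sigma_loc_um=est.sigma_loc_um,
                    loglik=est.log_likelihood,
                    method=est.method,
                )
            else:  # too short to estimate: reported, not silently dropped
                warnings_count += 1
                row.update(
                    d_um2_per_s=np.nan, sigma_loc_um=np.nan,
                    loglik=np.nan, method="unestimated",
                )
            row["confinement_diameter_um"] = confinement_diameter(t)
            row["d_cve"] = (
                cve_estimate(t, blur).d_um2_per_s if len(t) >= 3 else np.nan
            )
            rows.append(row)
        spt_path = out_dir / "spt_estimates.csv"
        df = pd.DataFrame(rows)
        df.to_csv(spt_path, index=False)
        outputs.append(spt_path)
        valid = df["d_um2_per_s"].dropna()
        if len(valid):
            summary["median_d_um2_per_s"] = float(valid.median())
            summary["median_confinement_um"] = float(
                df["confinement_diameter_um"].median()
            )

        # Statistical comparison of the two halves of the track set, as a
        # worked example of the stats layer on SPT output.
        if len(valid) >= 6:
            half = len(valid) // 2
            a, b = valid.iloc[:half].to_numpy(), valid.iloc[half:].to_numpy()
            u, p_u = mann_whitney_u(a, b)
            ks, p_ks = ks_two_sample(a, b)
            rout = rout_outliers(valid.to_numpy(), config.rout_q_percent)
            stats_path = out_dir / "stats.csv"
            pd.DataFrame(
                [
                    {"test": "mann_whitney_u", "statistic": u, "p": p_u,
                     "n_a": len(a), "n_b": len(b)},
                    {"test": "ks_two_sample", "statistic": ks, "p": p_ks,
                     "n_a": len(a), "n_b": len(b)},
                    {"test": "rout_outliers", "statistic": rout.n_flagged,
                     "p": np.nan, "n_a": len(valid), "n_b": 0},
                ]
            ).to_csv(stats_path, index=False)
            outputs.append(stats_path)

    summary_path = out_dir / "summary.json"
    write_json(summary_path, summary)
    outputs.append(summary_path)

    manifest = {
        "package": "synaptiq",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "coordinate_convention": "0-based row-major pixels; physical (x, y) ="
        " (col, row) * pixel_size_um at pixel centres; um/um2/s/um2_per_s",
        "inputs": {k: _sha256(Path(v)) for k, v in sorted(inputs.items())},
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        "warnings": warnings_count,
    }
    write_json(out_dir / "manifest.json", manifest)
    logger.info("pipeline complete: %d outputs in %s", len(outputs), out_dir)
    return out_dir
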