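"""Format codecs: TIFF image series, CSV tables, YAML specs, JSON sidecars.

Conventions (recorded in every run manifest): pixel indices are 0-based and
row-major; physical coordinates are pixel-centre in µm with
``(x, y) = (col, row) * pixel_size_um``; all distances are µm, areas µm²,
times s, diffusion coefficients µm²/s.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import ClusterSet, IntensityImage
from .synthetic import Trajectory

__all__ = [
    "read_image_series",
    "write_image_series",
    "write_mask",
    "write_cluster_table",
    "read_cluster_table",
    "read_tracks",
    "write_tracks",
    "write_json",
    "read_yaml",
]


def read_image_series(
    path: str | Path,
    pixel_size_um: float | None = None,
    channel_name: str = "",
    frame_interval_s: float | None = None,
) -> list[IntensityImage]:
    """Read a single- or multi-page TIFF as a time-ordered image list.

    Pixel size is taken from the TIFF resolution metadata when present;
    otherwise an explicit ``pixel_size_um`` is required.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if pixel_size_um is None:
            page = tif.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is not None and unit is not None and unit.value == 3:  # cm
                num, den = res.value
                if num:
                    pixel_size_um = 1e4 * den / num
    if pixel_size_um is None:
        raise ValueError(
            f"{path}: no pixel size in metadata; pass pixel_size_um explicitly"
        )
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 2-D or 3-D TIFF, got {data.shape}")
    return [
        IntensityImage(
            frame.astype(float),
            pixel_size_um,
            channel_name=channel_name,
            time_s=(i * frame_interval_s if frame_interval_s is not None else None),
        )
        for i, frame in enumerate(data)
    ]


def write_image_series(path: str | Path, images: list[IntensityImage]) -> None:
    """Write images as a float32 multi-page TIFF with resolution metadata."""
    stack = np.stack([img.pixels for img in images]).astype(np.float32)
    px_cm = 1e4 / images[0].pixel_size_um  # pixels per cm
    tifffile.imwrite(
        Path(path), stack, resolution=(px_cm, px_cm), resolutionunit=3
    )


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), mask.astype(np.uint8))


def write_cluster_table(
    path: str | Path, cluster_sets: list[ClusterSet], frames: list[int] | None = None
) -> pd.DataFrame:
    """Write one CSV row per cluster: frame, cluster_id, x_um, y_um,
    area_um2, total_intensity."""
    rows = []
    frames = frames if frames is not None else range(len(cluster_sets))
    for frame, cs in zip(frames, cluster_sets):
        for c in cs.clusters:
            rows.append(
                {
                    "frame": frame,
                    "cluster_id": c.id,
                    "x_um": c.centroid_um[0],
                    "y_um": c.centroid_um[1],
                    "area_um2": c.area_um2,
                    "total_intensity": c.total_intensity,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["frame", "cluster_id", "x_um", "y_um", "area_um2", "total_intensity"],
    )
    df.to_csv(Path(path), index=False)
    return df


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_tracks(path: str | Path, tracks: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for frame, (x, y) in enumerate(t.positions_um):
            rows.append(
                {"track_id": t.track_id, "frame": frame, "x_um": x, "y_um": y}
            )
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    df.to_csv(Path(path), index=False)
    return df


def read_tracks(path: str | Path, frame_interval_s: float) -> list[Trajectory]:
    """Read trajectories from CSV (track_id, frame, x_um, y_um).

    Frame gaps split a track into independent segments (with a warning);
    segments shorter than 2 positions are dropped.
    """
    df = pd.read_csv(Path(path))
    required = {"track_id", "frame", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"tracks CSV must have columns {sorted(required)}")
    tracks: list[Trajectory] = []
    next_id = 0
    for tid, group in df.groupby("track_id", sort=True):
        group = group.sort_values("frame")
        frames = group["frame"].to_numpy()
        pos = group[["x_um", "y_um"]].to_numpy(dtype=float)
        breaks = np.nonzero(np.diff(frames) != 1)[0]
        if breaks.size:
            warnings.warn(
                f"track {tid}: {breaks.size} frame gap(s); splitting into "
                f"{breaks.size + 1} segments",
                stacklevel=2,
            )
        for seg in np.split(np.arange(frames.size), breaks + 1):
            if seg.size >= 2:
                tracks.append(Trajectory(next_id, frame_interval_s, pos[seg]))
                next_id += 1
    return tracks


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
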