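"""Readers and writers for the pipeline's on-disk formats.

Images travel as single-channel TIFF (optionally multi-page for 3D) with a
JSON description tag carrying the pixel size in mm and channel metadata;
point sets and profiles travel as tidy CSV; sinograms as TIFF plus a JSON
sidecar with the angles; density grids as CSV matrices plus a JSON sidecar
with the grid geometry.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import CellPoints, ChannelVolume, DensityGrid, LineProfile, Sinogram

__all__ = [
    "read_volume",
    "write_volume",
    "read_points",
    "write_points",
    "read_profiles",
    "write_profiles",
    "write_ensemble",
    "read_density",
    "write_density",
    "read_sinogram",
    "write_sinogram",
]

log = logging.getLogger(__name__)


def write_volume(volume: ChannelVolume, path: str | Path) -> Path:
    """Write a channel volume as (multi-page) float32 TIFF with metadata."""
    path = Path(path)
    desc = json.dumps(
        {
            "pixel_size_mm": volume.pixel_size,
            "channel": volume.channel,
            "incubation_time_h": volume.incubation_time,
        }
    )
    tifffile.imwrite(path, volume.data.astype(np.float32), description=desc,
                     photometric="minisblack")
    return path


def read_volume(
    path: str | Path,
    pixel_size: float | None = None,
    channel: str | None = None,
) -> ChannelVolume:
    """Read a single-channel TIFF/OME-TIFF as a float volume.

    The pixel size comes from the JSON description tag if present; an
    explicit ``pixel_size`` argument always wins (with a logged warning on
    conflict). Missing in both places is a hard error. RGB/multi-sample
    TIFFs are rejected — each channel lives in its own file.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        if page.samplesperpixel > 1:
            raise ValueError(
                f"{path} has {page.samplesperpixel} samples per pixel; "
                "expected one single-channel grayscale image per file"
            )
        meta = {}
        desc = page.description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    file_ps = meta.get("pixel_size_mm")
    if pixel_size is not None:
        if file_ps is not None and not np.isclose(file_ps, pixel_size):
            log.warning(
                "pixel size conflict for %s: file says %g mm, config says %g mm; "
                "using config", path, file_ps, pixel_size,
            )
        ps = pixel_size
    elif file_ps is not None:
        ps = float(file_ps)
    else:
        raise ValueError(
            f"no pixel size in {path} metadata and none supplied; "
            "pass pixel_size explicitly"
        )
    return ChannelVolume(
        np.asarray(data, dtype=float),
        ps,
        channel=channel if channel is not None else meta.get("channel", ""),
        incubation_time=meta.get("incubation_time_h"),
    )


# ---------------------------------------------------------------------------
# points


def write_points(points: CellPoints, path: str | Path) -> Path:
    """Write cell points as CSV (slice_id, x_mm, y_mm) + JSON param sidecar."""
    path = Path(path)
    points.to_frame().to_csv(path, index=False, float_format="%.8g")
    if points.detection_params:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(points.detection_params, indent=2, sort_keys=True))
    return path


def read_points(path: str | Path, slice_id: str | None = None) -> CellPoints:
    df = pd.read_csv(path)
    if slice_id is not None:
        df = df[df["slice_id"].astype(str) == str(slice_id)]
    sid = str(df["slice_id"].iloc[0]) if len(df) else (slice_id or "0")
    return CellPoints(df["x_mm"].to_numpy(), df["y_mm"].to_numpy(), slice_id=sid)


# ---------------------------------------------------------------------------
# profiles


def write_profiles(profiles: list[LineProfile], path: str | Path) -> Path:
    """Tidy CSV: profile_id, condition, time_h, distance_mm, intensity."""
    frames = []
    for i, p in enumerate(profiles):
        frames.append(
            pd.DataFrame(
                {
                    "profile_id": i,
                    "condition": p.condition,
                    "time_h": p.incubation_time,
                    "distance_mm": p.distance,
                    "intensity": p.intensity,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        Path(path), index=False, float_format="%.8g"
    )
    return Path(path)


def read_profiles(path: str | Path) -> list[LineProfile]:
    df = pd.read_csv(path)
    profiles = []
    for _, grp in df.groupby("profile_id", sort=True):
        t = grp["time_h"].iloc[0]
        profiles.append(
            LineProfile(
                distance=grp["distance_mm"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                incubation_time=None if pd.isna(t) else float(t),
                condition=str(grp["condition"].iloc[0]),
            )
        )
    return profiles


def write_ensemble(ensemble, path: str | Path) -> Path:
    ensemble.to_frame().to_csv(Path(path), index=False, float_format="%.8g")
    return Path(path)


# ---------------------------------------------------------------------------
# density grids


def write_density(grid: DensityGrid, path: str | Path) -> Path:
    """Density values as a CSV matrix; geometry in a JSON sidecar."""
    path = Path(path)
    pd.DataFrame(grid.values).to_csv(path, index=False, header=False,
                                     float_format="%.8g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "origin_mm": list(grid.origin),
                "spacing_mm": grid.spacing,
                "k": grid.k,
                "display_floor": grid.display_floor,
                "display_ceiling": grid.display_ceiling,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return path


def read_density(path: str | Path) -> DensityGrid:
    path = Path(path)
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return DensityGrid(
        origin=tuple(meta["origin_mm"]),
        spacing=float(meta["spacing_mm"]),
        values=values,
        k=int(meta["k"]),
        display_floor=float(meta["display_floor"]),
        display_ceiling=float(meta["display_ceiling"]),
    )


# ---------------------------------------------------------------------------
# sinograms


def write_sinogram(sino: Sinogram, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, sino.projections.astype(np.float32),
                     photometric="minisblack")
    path.with_suffix(".json").write_text(
        json.dumps(
            {"angles_deg": sino.angles.tolist(), "pixel_size_mm": sino.pixel_size},
            sort_keys=True,
        )
    )
    return path


def read_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    proj = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Sinogram(
        projections=proj,
        angles=np.asarray(meta["angles_deg"], dtype=float),
        pixel_size=float(meta["pixel_size_mm"]),
    )
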