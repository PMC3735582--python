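"""Run configuration and the end-to-end pipeline driver.

A run is described by a single flat JSON document (:class:`RunConfig`);
unknown keys anywhere in it are rejected before any computation. The
driver executes the requested stages in order and writes every artifact
plus a machine-readable provenance record (canonical-config hash, seed,
library versions, per-stage summaries) so a run is reproducible from the
record alone. No stage mutates its input files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np

from . import corrections, density, detect, io, opt_sim, synthetic
from .types import ChannelVolume

__all__ = ["RunConfig", "run_pipeline", "STAGE_DEFAULTS"]

STAGE_DEFAULTS: dict[str, dict[str, Any]] = {
    "phantom": {
        "shape": [256, 256],
        "background_level": 100.0,
        "noise_sd": 5.0,
        "bias_amplitude": 0.2,
        "punctate_count": 50,
        "punctate_amplitude": 1000.0,
        "alpha_true": 0.7,
    },
    "cells": {
        "lam": 15.0,           # cells/mm^2, homogeneous
        "psf_sigma_mm": 0.05,
        "amplitude": 100.0,
    },
    "corrections": {
        "hp_size": 3,
        "sd_window": 15,
        "threshold_sd": 5.0,
        "max_component_size": 2,
        "bias_order": 3,
        "foreground_quantile": 0.95,
        "trim_sd": 3.0,
    },
    "detect": {
        "sigma_mm": 0.05,
        "intensity_threshold": 25.0,
        "threshold_is_quantile": False,
        "rank_radius": 5,
        "rank_percentile": 99.0,
    },
    "density": {
        "k": 8,
        "spacing_mm": 0.5,
        "display_floor": 30.0,
        "display_ceiling": 1200.0,
        "per_cell_area": True,
        "bias_correction": False,
    },
    "opt": {
        "n_views": 360,
        "filter_name": "hann",
    },
}

_DEFAULT_STAGES = ["simulate", "correct", "detect", "density"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run; see :data:`STAGE_DEFAULTS` for the
    per-stage keys and their defaults."""

    output_dir: str = "stain3d_run"
    seed: int = 0
    pixel_size: float = 0.02
    stages: list[str] = field(default_factory=lambda: list(_DEFAULT_STAGES))
    inputs: dict[str, str] = field(default_factory=dict)
    phantom: dict[str, Any] = field(default_factory=dict)
    cells: dict[str, Any] = field(default_factory=dict)
    corrections: dict[str, Any] = field(default_factory=dict)
    detect: dict[str, Any] = field(default_factory=dict)
    density: dict[str, Any] = field(default_factory=dict)
    opt: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known_stages = {"simulate", "reconstruct", "correct", "detect", "density"}
        unknown = set(self.stages) - known_stages
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for stage, defaults in STAGE_DEFAULTS.items():
            supplied = getattr(self, stage)
            bad = set(supplied) - set(defaults)
            if bad:
                raise ValueError(f"unknown keys {sorted(bad)} in '{stage}' config")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        names = {f.name for f in fields(cls)}
        bad = set(d) - names
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        return cls(**d)

    def stage_params(self, stage: str) -> dict[str, Any]:
        """Stage defaults overridden by this config's entries."""
        return {**STAGE_DEFAULTS[stage], **getattr(self, stage)}

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _canonical_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and write all artifacts.

    Stage order is fixed: simulate -> (reconstruct) -> correct -> detect ->
    density; only the stages listed in ``config.stages`` run. Without a
    ``simulate`` stage, input TIFF paths must be given in ``config.inputs``
    (keys ``stain`` and ``auto``). Returns the provenance record, which is
    also written to ``<output_dir>/run_report.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries: dict[str, Any] = {}
    artifacts: dict[str, str] = {}
    stain: ChannelVolume | None = None
    auto: ChannelVolume | None = None

    try:
        if "simulate" in config.stages:
            stain, auto = _stage_simulate(config, out, summaries, artifacts)
        else:
            if "stain" not in config.inputs:
                raise ValueError("no simulate stage and no 'stain' input path")
            stain = io.read_volume(config.inputs["stain"], pixel_size=config.pixel_size)
            if "auto" in config.inputs:
                auto = io.read_volume(config.inputs["auto"], pixel_size=config.pixel_size)

        if "reconstruct" in config.stages:
            stain = _stage_reconstruct(config, stain, out, summaries, artifacts)

        if "correct" in config.stages:
            stain, auto = _stage_correct(config, stain, auto, out, summaries, artifacts)

        points = None
        if "detect" in config.stages:
            points = _stage_detect(config, stain, out, summaries, artifacts)

        if "density" in config.stages:
            if points is None:
                if "points" not in config.inputs:
                    raise ValueError("density stage needs detected points or a 'points' input")
                points = io.read_points(config.inputs["points"])
            _stage_density(config, points, out, summaries, artifacts)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    import pandas
    import scipy
    import skimage
    import sklearn

    from . import __version__

    record = {
        "config": config.to_dict(),
        "config_sha256": _canonical_hash(config),
        "seed": config.seed,
        "versions": {
            "stain3d": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "scikit-learn": sklearn.__version__,
            "pandas": pandas.__version__,
        },
        "stages": summaries,
        "artifacts": artifacts,
    }
    (out / "run_report.json").write_text(json.dumps(record, indent=2, sort_keys=True))
    return record


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config, out, summaries, artifacts):
    p = config.stage_params("phantom")
    c = config.stage_params("cells")
    shape = tuple(p["shape"])
    # pixel-center extent: points must land on the image grid
    region = ((shape[1] - 1) * config.pixel_size, (shape[0] - 1) * config.pixel_size)

    pattern, _ = synthetic.generate_point_pattern(
        synthetic.PointPatternSpec(region=region, intensity=float(c["lam"]),
                                   seed=config.seed)
    )
    cells_img = synthetic.render_cells(
        pattern, shape, config.pixel_size, psf_sigma=c["psf_sigma_mm"],
        amplitude=c["amplitude"],
    )
    spec = synthetic.PhantomSpec(
        shape=shape,
        pixel_size=config.pixel_size,
        seed=config.seed,
        background_level=p["background_level"],
        noise_sd=p["noise_sd"],
        bias_amplitude=p["bias_amplitude"],
        punctate_count=p["punctate_count"],
        punctate_amplitude=p["punctate_amplitude"],
        alpha_true=p["alpha_true"],
    )
    phantom = synthetic.generate_phantom(spec, stain_image=cells_img.data)

    artifacts["stain"] = io.write_volume(phantom.stain, out / "stain.tif").name
    artifacts["auto"] = io.write_volume(phantom.auto, out / "auto.tif").name
    artifacts["points_true"] = io.write_points(pattern, out / "points_true.csv").name
    truth = {
        "alpha_true": phantom.alpha_true,
        "punctate_rc": phantom.punctate_rc.tolist(),
        "n_true_cells": len(pattern),
        "lam_true": float(c["lam"]),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    artifacts["truth"] = "truth.json"
    summaries["simulate"] = {"n_true_cells": len(pattern),
                             "punctate_count": int(len(phantom.punctate_rc))}
    return phantom.stain, phantom.auto


def _stage_reconstruct(config, stain, out, summaries, artifacts):
    o = config.stage_params("opt")
    angles = opt_sim.view_angles(int(o["n_views"]))
    sino = opt_sim.forward_project(stain, angles)
    recon = opt_sim.fbp_reconstruct(sino, filter_name=o["filter_name"])
    artifacts["sinogram"] = io.write_sinogram(sino, out / "sinogram.tif").name
    artifacts["reconstruction"] = io.write_volume(recon, out / "reconstruction.tif").name
    summaries["reconstruct"] = {"n_views": int(o["n_views"]),
                                "filter": o["filter_name"]}
    return recon


def _stage_correct(config, stain, auto, out, summaries, artifacts):
    cp = config.stage_params("corrections")
    mask = corrections.detect_punctate(
        stain, hp_size=cp["hp_size"], sd_window=cp["sd_window"],
        threshold_sd=cp["threshold_sd"], max_component_size=cp["max_component_size"],
    )
    stain = corrections.remove_punctate(stain, mask)
    summary = {"punctate_flagged": mask.count}

    if auto is not None:
        scale = corrections.estimate_background_scale(
            stain, auto, foreground_quantile=cp["foreground_quantile"],
            trim_sd=cp["trim_sd"],
        )
        stain, clip_frac = corrections.subtract_background(stain, auto, scale)
        summary["background_scale"] = scale
        summary["clipping_fraction"] = clip_frac

        offset = float(min(0.0, auto.data.min()))
        shifted = ChannelVolume(auto.data - offset + (1.0 if offset < 0 else 0.0),
                                auto.pixel_size, channel=auto.channel)
        if shifted.data.min() > 0:
            bias = corrections.estimate_bias(shifted, order=cp["bias_order"])
            auto = corrections.correct_bias(auto, bias)
            artifacts["auto_corrected"] = io.write_volume(
                auto, out / "auto_corrected.tif"
            ).name
            summary["bias_field_range"] = [float(bias.values.min()),
                                           float(bias.values.max())]

    artifacts["stain_corrected"] = io.write_volume(stain, out / "stain_corrected.tif").name
    summaries["correct"] = summary
    return stain, auto


def _stage_detect(config, stain, out, summaries, artifacts):
    dp = config.stage_params("detect")
    points = detect.detect_cells(
        stain,
        sigma=dp["sigma_mm"],
        intensity_threshold=dp["intensity_threshold"],
        rank_radius=dp["rank_radius"],
        rank_percentile=dp["rank_percentile"],
        threshold_is_quantile=dp["threshold_is_quantile"],
    )
    artifacts["points"] = io.write_points(points, out / "points.csv").name
    summaries["detect"] = {"n_cells": len(points)}
    return points


def _stage_density(config, points, out, summaries, artifacts):
    gp = config.stage_params("density")
    grid = density.knn_density(
        points,
        spacing=gp["spacing_mm"],
        k=int(gp["k"]),
        per_cell_area=gp["per_cell_area"],
        bias_correction=gp["bias_correction"],
        display_floor=gp["display_floor"],
        display_ceiling=gp["display_ceiling"],
    )
    artifacts["density"] = io.write_density(grid, out / "density.csv").name
    import imageio.v3 as iio

    iio.imwrite(out / "density.png", density.render_density(grid))
    artifacts["density_png"] = "density.png"
    finite = grid.values[np.isfinite(grid.values)]
    summaries["density"] = {
        "n_nodes": int(grid.values.size),
        "median_density": float(np.median(finite)) if finite.size else None,
    }
    return grid
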