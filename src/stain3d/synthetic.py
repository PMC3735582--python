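"""Synthetic two-channel phantoms with known ground truth.

Everything the pipeline consumes can be generated here with seeded
randomness: 1-D tracer penetration fronts at multiple incubation times, an
anatomy-like autofluorescence channel that bleeds into the stain channel at
a known scale, a smooth multiplicative bias field, isolated punctate
artifacts, and spatial Poisson point patterns of cells with region-varying
density.

All randomness flows from one top-level integer seed through named
substreams (``geometry``, ``noise``, ``punctate``, ``points``) so each
stage of a phantom is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage, special

from .types import CellPoints, ChannelVolume

__all__ = [
    "PhantomSpec",
    "DiffusionSpec",
    "PointPatternSpec",
    "Phantom",
    "simulate_diffusion_profile",
    "generate_phantom",
    "generate_point_pattern",
    "render_cells",
    "default_structures",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of a top-level seed.

    The stream key is derived from a CRC32 of the name, so it is stable
    across processes and Python hash randomization.
    """
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# specs


@dataclass
class DiffusionSpec:
    """Conditions of a tracer penetration experiment.

    D is the effective diffusivity in mm^2/h, C0 the edge concentration in
    arbitrary intensity units, ``times`` the incubation durations in hours.
    ``hindered=True`` switches to a binding-limited regime producing a sharp
    front instead of the free erfc profile. ``retardation`` divides the
    diffusivity in the hindered regime and ``front_boost`` sets how much of
    the profile saturates at the binding capacity (larger -> sharper front).
    """

    D: float = 0.01
    C0: float = 1.0
    times: Sequence[float] = (5.0, 10.0, 24.0, 48.0)
    hindered: bool = False
    noise_sd: float = 0.0
    retardation: float = 25.0
    front_boost: float = 4.0

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError("D must be positive")
        if any(t <= 0 for t in self.times):
            raise ValueError("all incubation times must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.retardation < 1:
            raise ValueError("retardation must be >= 1")


@dataclass
class PhantomSpec:
    """Parameters of a two-channel (stain + autofluorescence) image phantom."""

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.02
    seed: int = 0
    background_level: float = 100.0
    noise_sd: float = 5.0
    bias_amplitude: float = 0.2
    punctate_count: int = 50
    punctate_amplitude: float = 1000.0
    alpha_true: float = 0.7

    def __post_init__(self) -> None:
        if any(s < 32 for s in self.shape):
            raise ValueError("each phantom dimension must be >= 32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.punctate_count < 0:
            raise ValueError("punctate_count must be non-negative")
        if self.alpha_true < 0:
            raise ValueError("alpha_true must be non-negative")
        if not 0 <= self.bias_amplitude < 0.9:
            raise ValueError("bias_amplitude must be in [0, 0.9)")


@dataclass
class PointPatternSpec:
    """Inhomogeneous Poisson point pattern on a rectangular region.

    ``region`` is (width_mm, height_mm); ``intensity`` is either a constant,
    a callable lambda(x, y) in cells/mm^2 (vectorized over arrays), or a 2D
    grid of densities covering the region row-major (row 0 at y=0).
    """

    region: tuple[float, float]
    intensity: float | np.ndarray | Callable[[np.ndarray, np.ndarray], np.ndarray]
    seed: int = 0
    resolution: int = 128

    def __post_init__(self) -> None:
        if self.region[0] <= 0 or self.region[1] <= 0:
            raise ValueError("region area must be positive")


@dataclass
class Phantom:
    """A generated phantom: the two observed channels plus ground truth."""

    stain: ChannelVolume
    auto: ChannelVolume
    clean_stain: np.ndarray
    auto_clean: np.ndarray
    bias_field: np.ndarray
    punctate_rc: np.ndarray  # (n, 2) row/col pixel indices
    punctate_values: np.ndarray
    alpha_true: float
    spec: PhantomSpec = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# diffusion fronts


def simulate_diffusion_profile(
    spec: DiffusionSpec,
    t: float,
    x: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Simulated 1-D tracer intensity at depths ``x`` (mm) after time ``t`` (h).

    Free regime: semi-infinite diffusion from a constant-concentration edge,
    C(x, t) = C0 * erfc(x / (2 sqrt(D t))). Hindered regime: retarded
    diffusion with instantaneous immobile binding, realized as the free
    solution with diffusivity D/R boosted by ``front_boost`` and clipped at
    the binding capacity C0 — a saturated band behind a near-step front whose
    position grows like sqrt(t).

    Additive Gaussian noise of SD ``spec.noise_sd`` is drawn from the
    ``noise`` substream of ``seed``.
    """
    if t <= 0:
        raise ValueError("incubation time must be positive")
    if not any(np.isclose(t, ti) for ti in spec.times):
        raise ValueError(f"t={t} is not one of the spec's incubation times {spec.times}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("depths must be non-negative")

    if spec.hindered:
        d_eff = spec.D / spec.retardation
        profile = np.minimum(
            spec.C0,
            spec.front_boost * spec.C0 * special.erfc(x / (2.0 * np.sqrt(d_eff * t))),
        )
    else:
        profile = spec.C0 * special.erfc(x / (2.0 * np.sqrt(spec.D * t)))

    if spec.noise_sd > 0:
        profile = profile + substream(seed, "noise").normal(0.0, spec.noise_sd, x.shape)
    return profile


# ---------------------------------------------------------------------------
# image phantoms


def default_structures(shape: tuple[int, int]) -> list[dict]:
    """A small anatomy-like structure set scaled to the image shape.

    The autofluorescence channel gets one large tissue ellipse plus two
    internal bands (mimicking ventricle-scale anatomy); the stain channel
    gets three compact foci inside the tissue.
    """
    h, w = shape
    return [
        {"kind": "ellipse", "center": (h / 2, w / 2), "size": (0.42 * h, 0.42 * w),
         "intensity": 120.0, "channel": "auto"},
        {"kind": "ellipse", "center": (0.40 * h, 0.45 * w), "size": (0.10 * h, 0.18 * w),
         "intensity": 60.0, "channel": "auto"},
        {"kind": "disk", "center": (0.62 * h, 0.60 * w), "size": 0.08 * min(h, w),
         "intensity": 80.0, "channel": "auto"},
        {"kind": "disk", "center": (0.35 * h, 0.62 * w), "size": 0.06 * min(h, w),
         "intensity": 150.0, "channel": "stain"},
        {"kind": "disk", "center": (0.60 * h, 0.38 * w), "size": 0.05 * min(h, w),
         "intensity": 200.0, "channel": "stain"},
        {"kind": "ellipse", "center": (0.50 * h, 0.50 * w), "size": (0.04 * h, 0.10 * w),
         "intensity": 120.0, "channel": "stain"},
    ]


def _rasterize(shape: tuple[int, int], structures: list[dict], channel: str) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    img = np.zeros(shape, dtype=float)
    for s in structures:
        if s.get("channel", "stain") != channel:
            continue
        r0, c0 = s["center"]
        if s["kind"] == "disk":
            rad = float(s["size"])
            ra = ca = rad
            inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        elif s["kind"] == "ellipse":
            ra, ca = s["size"]
            inside = ((rr - r0) / ra) ** 2 + ((cc - c0) / ca) ** 2 <= 1.0
        elif s["kind"] == "box":
            ra, ca = s["size"]
            inside = (np.abs(rr - r0) <= ra) & (np.abs(cc - c0) <= ca)
        else:
            raise ValueError(f"unknown structure kind {s['kind']!r}")
        if r0 - ra < 0 or r0 + ra > h - 1 or c0 - ca < 0 or c0 + ca > w - 1:
            raise ValueError("structure geometry does not fit within the image shape")
        img[inside] += float(s["intensity"])
    return img


def _bias_field(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Random smooth multiplicative field: quadratic in normalized coords,
    rescaled to the requested peak-to-mean amplitude and mean 1."""
    if amplitude == 0:
        return np.ones(shape)
    h, w = shape
    u = np.linspace(-1.0, 1.0, h)[:, None]
    v = np.linspace(-1.0, 1.0, w)[None, :]
    coef = rng.normal(size=5)
    raw = coef[0] * u + coef[1] * v + coef[2] * u * v + coef[3] * u**2 + coef[4] * v**2
    span = np.max(np.abs(raw))
    if span == 0:
        return np.ones(shape)
    bias = 1.0 + amplitude * raw / span
    return bias / bias.mean()


def _place_punctate(
    shape: tuple[int, int],
    count: int,
    rng: np.random.Generator,
    min_separation: int = 3,
    margin: int = 4,
) -> np.ndarray:
    """Random isolated pixel positions, pairwise Chebyshev distance >= 3."""
    if count == 0:
        return np.empty((0, 2), dtype=int)
    h, w = shape
    taken: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = 1000 * count
    while len(taken) < count:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {count} isolated punctate pixels with "
                f"separation >= {min_separation} in shape {shape}"
            )
        attempts += 1
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if all(max(abs(r - r0), abs(c - c0)) >= min_separation for r0, c0 in taken):
            taken.append((r, c))
    return np.array(taken, dtype=int)


def generate_phantom(
    spec: PhantomSpec,
    structures: list[dict] | None = None,
    stain_image: np.ndarray | None = None,
) -> Phantom:
    """Generate a paired stain/autofluorescence phantom with ground truth.

    Composition of the observed channels:

    * ``auto  = auto_clean + noise_a`` where ``auto_clean`` is the smoothed
      anatomy plus the background level;
    * ``stain = bias * clean_stain + alpha_true * auto + punctate + noise_s``.

    The returned :class:`Phantom` carries ``clean_stain``, ``auto_clean``,
    the bias field, the punctate pixel coordinates/values and ``alpha_true``
    so every correction stage can be scored against truth.

    ``stain_image``, if given, replaces the rasterized stain structures as
    the clean stain (used e.g. to inject rendered cell spots).
    """
    if structures is None:
        structures = default_structures(spec.shape)

    geometry_rng = substream(spec.seed, "geometry")
    noise_rng = substream(spec.seed, "noise")
    punctate_rng = substream(spec.seed, "punctate")

    smooth_px = max(2.0, min(spec.shape) / 64.0)
    auto_clean = spec.background_level + ndimage.gaussian_filter(
        _rasterize(spec.shape, structures, "auto"), smooth_px
    )
    if stain_image is not None:
        clean_stain = np.asarray(stain_image, dtype=float)
        if clean_stain.shape != tuple(spec.shape):
            raise ValueError("stain_image shape must match the phantom shape")
    else:
        clean_stain = ndimage.gaussian_filter(
            _rasterize(spec.shape, structures, "stain"), smooth_px / 2.0
        )

    bias = _bias_field(spec.shape, spec.bias_amplitude, geometry_rng)

    punctate_rc = _place_punctate(spec.shape, spec.punctate_count, punctate_rng)
    punctate_img = np.zeros(spec.shape)
    punctate_values = np.full(len(punctate_rc), float(spec.punctate_amplitude))
    if len(punctate_rc):
        punctate_img[punctate_rc[:, 0], punctate_rc[:, 1]] = punctate_values

    noise_a = noise_rng.normal(0.0, spec.noise_sd, spec.shape) if spec.noise_sd else 0.0
    auto_obs = auto_clean + noise_a
    noise_s = noise_rng.normal(0.0, spec.noise_sd, spec.shape) if spec.noise_sd else 0.0
    stain_obs = bias * clean_stain + spec.alpha_true * auto_obs + punctate_img + noise_s

    return Phantom(
        stain=ChannelVolume(stain_obs, spec.pixel_size, channel="stain"),
        auto=ChannelVolume(auto_obs, spec.pixel_size, channel="auto"),
        clean_stain=clean_stain,
        auto_clean=np.asarray(auto_clean, dtype=float),
        bias_field=bias,
        punctate_rc=punctate_rc,
        punctate_values=punctate_values,
        alpha_true=spec.alpha_true,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# point patterns


def _intensity_grid(spec: PointPatternSpec) -> tuple[np.ndarray, float, float]:
    """Evaluate the intensity on a fine grid; returns (grid, dx, dy)."""
    wx, wy = spec.region
    nx = spec.resolution
    ny = max(1, int(round(spec.resolution * wy / wx)))
    if isinstance(spec.intensity, np.ndarray):
        lam = np.asarray(spec.intensity, dtype=float)
        ny, nx = lam.shape
    else:
        dx, dy = wx / nx, wy / ny
        xc = (np.arange(nx) + 0.5) * dx
        yc = (np.arange(ny) + 0.5) * dy
        if callable(spec.intensity):
            lam = np.asarray(spec.intensity(xc[None, :], yc[:, None]), dtype=float)
            lam = np.broadcast_to(lam, (ny, nx)).copy()
        else:
            lam = np.full((ny, nx), float(spec.intensity))
    if np.any(lam < 0):
        raise ValueError("intensity must be non-negative everywhere")
    return lam, wx / lam.shape[1], wy / lam.shape[0]


def generate_point_pattern(spec: PointPatternSpec) -> tuple[CellPoints, np.ndarray]:
    """Realize an inhomogeneous Poisson process on the region.

    The region is tiled by the intensity grid; each tile receives a
    Poisson(lambda * dA) count with points placed uniformly inside the tile,
    so the expected total count is the integral of lambda over the region.

    Returns the points (mm coordinates) and the intensity grid used.
    """
    lam, dx, dy = _intensity_grid(spec)
    rng = substream(spec.seed, "points")
    counts = rng.poisson(lam * dx * dy)
    total = int(counts.sum())
    xs = np.empty(total)
    ys = np.empty(total)
    idx = 0
    nz = np.argwhere(counts > 0)
    for i, j in nz:
        n = counts[i, j]
        xs[idx : idx + n] = (j + rng.random(n)) * dx
        ys[idx : idx + n] = (i + rng.random(n)) * dy
        idx += n
    return CellPoints(xs, ys, slice_id="synthetic"), lam


def render_cells(
    points: CellPoints,
    shape: tuple[int, int],
    pixel_size: float,
    psf_sigma: float,
    amplitude: float = 1.0,
) -> ChannelVolume:
    """Render a point pattern as a sum of Gaussian spots.

    ``psf_sigma`` is in mm; an isolated spot peaks at ``amplitude``. Spots
    are accumulated on local patches out to 5 sigma for speed.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    h, w = shape
    img = np.zeros(shape, dtype=float)
    sig_px = psf_sigma / pixel_size
    halo = int(np.ceil(5 * sig_px))
    for x, y in zip(points.x, points.y):
        c = x / pixel_size
        r = y / pixel_size
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValueError(f"point ({x}, {y}) mm lies outside the image extent")
        r0, r1 = max(0, int(r) - halo), min(h, int(r) + halo + 2)
        c0, c1 = max(0, int(c) - halo), min(w, int(c) + halo + 2)
        rr = np.arange(r0, r1)[:, None]
        cc = np.arange(c0, c1)[None, :]
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sig_px**2)
        )
    return ChannelVolume(img, pixel_size, channel="cells")
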