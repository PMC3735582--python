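"""Tracer-penetration profiling from slice images.

The analysis mirrors the classical way penetration of a diffusing label is
quantified: sample intensity along lines normal to the tissue edge, running
inward; normalize the distance axis by the square root of the incubation
time (free diffusion is self-similar in x/sqrt(t)); normalize each curve's
amplitude by the value at the tissue edge estimated from a third-order
polynomial fit; then average the equivalent curves and attach a pointwise
90% confidence band.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats
from skimage import filters, measure

from .types import ChannelVolume, LineProfile, ProfileEnsemble

__all__ = [
    "DegenerateProfileError",
    "find_edge",
    "extract_profiles",
    "normalize_distance",
    "normalize_amplitude",
    "average_ensemble",
    "plot_ensemble",
]


class DegenerateProfileError(ValueError):
    """Raised when the fitted edge amplitude is non-positive."""


def find_edge(image: ChannelVolume, smooth_px: float = 2.0) -> np.ndarray:
    """Locate the tissue boundary of a 2D slice.

    Otsu threshold on a lightly smoothed image, keep the largest connected
    component, and return its longest contour as an (n, 2) polyline in
    (row, col) pixel coordinates.
    """
    img = image.data if image.data.ndim == 2 else image.data[0]
    smoothed = ndimage.gaussian_filter(img, smooth_px)
    mask = smoothed > filters.threshold_otsu(smoothed)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no foreground found by Otsu thresholding")
    largest = np.argmax(ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))) + 1
    contours = measure.find_contours((labels == largest).astype(float), 0.5)
    return max(contours, key=len)


def _resample_polyline(polyline: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Return ``n`` evenly spaced points along the polyline and unit tangents."""
    pts = np.asarray(polyline, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    if arclen[-1] == 0:
        raise ValueError("edge polyline has zero length")
    # for a closed polyline, avoid duplicating the endpoint sample
    closed = np.allclose(pts[0], pts[-1])
    targets = np.linspace(0, arclen[-1], n, endpoint=not closed)
    rows = np.interp(targets, arclen, pts[:, 0])
    cols = np.interp(targets, arclen, pts[:, 1])
    samples = np.column_stack([rows, cols])
    # central-difference tangents along the resampled curve
    tang = np.gradient(samples, axis=0)
    norms = np.linalg.norm(tang, axis=1)
    norms[norms == 0] = 1.0
    return samples, tang / norms[:, None]


def extract_profiles(
    image: ChannelVolume,
    edge: np.ndarray | None = None,
    n_lines: int = 20,
    depth: float = 1.0,
    condition: str = "",
) -> list[LineProfile]:
    """Sample intensity along inward normals at evenly spaced edge points.

    Parameters
    ----------
    image:
        2D slice (or 3D volume, in which case the first slice is used).
    edge:
        (n, 2) polyline in (row, col) pixel coordinates; if ``None`` it is
        derived by Otsu thresholding (:func:`find_edge`).
    n_lines:
        Number of profiles, spread evenly along the edge arclength.
    depth:
        Sampling depth in mm; sample spacing equals the pixel size
        (bilinear interpolation between pixels).

    Normals are oriented toward the centroid of the edge polyline (the
    tissue interior for the convex-ish sections this targets). A normal
    that exits the image before ``depth`` yields a truncated, flagged
    profile rather than an error.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    img = image.data if image.data.ndim == 2 else image.data[0]
    if edge is None:
        edge = find_edge(image)
    edge = np.asarray(edge, dtype=float)
    if (
        np.any(edge < -0.5)
        or np.any(edge[:, 0] > img.shape[0] - 0.5)
        or np.any(edge[:, 1] > img.shape[1] - 0.5)
    ):
        raise ValueError("edge polyline must lie within the image")

    samples, tangents = _resample_polyline(edge, n_lines)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    centroid = edge.mean(axis=0)
    flip = np.sum((centroid[None, :] - samples) * normals, axis=1) < 0
    normals[flip] *= -1.0

    n_samples = int(np.floor(depth / image.pixel_size)) + 1
    steps = np.arange(n_samples)  # in pixels
    profiles: list[LineProfile] = []
    for (r0, c0), (nr, nc) in zip(samples, normals):
        rr = r0 + steps * nr
        cc = c0 + steps * nc
        inside = (rr >= 0) & (rr <= img.shape[0] - 1) & (cc >= 0) & (cc <= img.shape[1] - 1)
        if inside.all():
            stop = n_samples
        else:
            stop = int(np.argmin(inside))  # first sample outside
        if stop < 2:
            continue
        vals = ndimage.map_coordinates(
            img, np.vstack([rr[:stop], cc[:stop]]), order=1, mode="nearest"
        )
        profiles.append(
            LineProfile(
                distance=steps[:stop] * image.pixel_size,
                intensity=vals,
                incubation_time=image.incubation_time,
                condition=condition,
                truncated=stop < n_samples,
            )
        )
    return profiles


def normalize_distance(profile: LineProfile) -> LineProfile:
    """Scale the distance axis by 1/sqrt(incubation time).

    Free-diffusion profiles taken at different times coincide on the scaled
    axis x/sqrt(t); intensities are left untouched.
    """
    if profile.incubation_time is None or profile.incubation_time <= 0:
        raise ValueError("profile needs a positive incubation_time")
    return LineProfile(
        distance=profile.distance / np.sqrt(profile.incubation_time),
        intensity=profile.intensity.copy(),
        incubation_time=profile.incubation_time,
        condition=profile.condition,
        scaled=True,
        truncated=profile.truncated,
    )


def normalize_amplitude(profile: LineProfile, window_frac: float = 0.25) -> LineProfile:
    """Divide intensities by the edge amplitude from a cubic fit.

    A third-order polynomial is fit by least squares to the near-edge
    window (first ``window_frac`` of the profile depth, at least 4 samples)
    and evaluated at distance 0; the whole curve is divided by that value.
    The fitted amplitude must be positive.

    The operation is idempotent: on an already-normalized profile the
    refit origin value is exactly 1.
    """
    if len(profile.distance) < 4:
        raise ValueError("need at least 4 samples for a cubic fit")
    if not 0 < window_frac <= 1:
        raise ValueError("window_frac must be in (0, 1]")
    cutoff = window_frac * profile.distance[-1]
    sel = profile.distance <= cutoff
    if sel.sum() < 4:
        sel = np.zeros_like(sel)
        sel[:4] = True
    coeffs = np.polynomial.polynomial.polyfit(
        profile.distance[sel], profile.intensity[sel], deg=3
    )
    origin = float(np.polynomial.polynomial.polyval(0.0, coeffs))
    if origin <= 0:
        raise DegenerateProfileError(
            f"fitted origin amplitude {origin:.4g} is not positive"
        )
    return LineProfile(
        distance=profile.distance.copy(),
        intensity=profile.intensity / origin,
        incubation_time=profile.incubation_time,
        condition=profile.condition,
        scaled=profile.scaled,
        truncated=profile.truncated,
    )


def average_ensemble(
    profiles: list[LineProfile],
    allow_mixed_conditions: bool = False,
) -> ProfileEnsemble:
    """Average normalized profiles on a common grid with a 90% t-band.

    The common grid is the union of all profiles' distance samples clipped
    to the shortest profile; each curve is linearly interpolated onto it.
    The band is the pointwise Student-t 90% confidence interval of the mean.
    Profiles with differing condition labels raise unless
    ``allow_mixed_conditions`` is set.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to average")
    conditions = {p.condition for p in profiles}
    if len(conditions) > 1 and not allow_mixed_conditions:
        raise ValueError(
            f"mixed condition labels {sorted(conditions)}; "
            "pass allow_mixed_conditions=True to combine them"
        )
    shortest = min(p.distance[-1] for p in profiles)
    grid = np.unique(np.concatenate([p.distance for p in profiles]))
    grid = grid[grid <= shortest]
    stack = np.vstack([np.interp(grid, p.distance, p.intensity) for p in profiles])

    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    half = stats.t.ppf(0.95, df=n - 1) * sd / np.sqrt(n)
    return ProfileEnsemble(
        scaled_distance=grid,
        mean_intensity=mean,
        ci90_low=mean - half,
        ci90_high=mean + half,
        n_profiles=n,
        condition=profiles[0].condition if len(conditions) == 1 else "mixed",
    )


def plot_ensemble(ensembles, path, labels=None):
    """Plot one or more ensembles (mean curve + shaded 90% band) to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not isinstance(ensembles, (list, tuple)):
        ensembles = [ensembles]
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, ens in enumerate(ensembles):
        label = labels[i] if labels else (ens.condition or f"ensemble {i}")
        ax.plot(ens.scaled_distance, ens.mean_intensity, label=label)
        ax.fill_between(ens.scaled_distance, ens.ci90_low, ens.ci90_high, alpha=0.3)
    ax.set_xlabel(r"distance / $\sqrt{t}$  (mm h$^{-1/2}$)")
    ax.set_ylabel("normalized intensity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
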