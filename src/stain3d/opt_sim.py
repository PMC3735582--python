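"""Parallel-beam projection and reconstruction plumbing.

Optical projection tomography with telecentric optics is well approximated
by parallel-beam geometry, so the synthetic end-to-end chain uses a
discrete Radon transform for acquisition and ramp-filtered back-projection
(FBP) for reconstruction. This module exists to exercise the downstream
correction/detection/density stages on reconstructed images; it does not
model scatter, attenuation or focal depth.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import iradon, radon

from .types import ChannelVolume, Sinogram

__all__ = ["forward_project", "fbp_reconstruct", "view_angles"]


def view_angles(n_views: int) -> np.ndarray:
    """``n_views`` angles evenly covering [0, 360) degrees."""
    return np.arange(n_views) * (360.0 / n_views)


def forward_project(volume: ChannelVolume, angles: np.ndarray) -> Sinogram:
    """Line integrals of a square 2D slice at the given view angles (degrees).

    The slice content should lie within the inscribed circle of the image
    (the usual tomographic support); bilinear sampling is used. Returns a
    detector-position x angle sinogram.
    """
    img = volume.data
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("forward projection requires a square 2D slice")
    angles = np.asarray(angles, dtype=float)
    if np.any(angles < 0) or np.any(angles >= 360):
        raise ValueError("angles must lie in [0, 360)")
    proj = radon(img, theta=angles, circle=True, preserve_range=True)
    return Sinogram(projections=proj, angles=angles, pixel_size=volume.pixel_size)


def fbp_reconstruct(
    sino: Sinogram,
    filter_name: str = "hann",
    output_size: int | None = None,
) -> ChannelVolume:
    """Filtered back-projection of a sinogram onto the original grid.

    ``filter_name`` is ``"hann"`` (ramp with Hann apodization, default) or
    ``"ramp"``. At least 8 views are required; for quantitative work use
    hundreds. Sinogram intensities are scaled by the pixel size inverse
    internally so the reconstruction returns to image units.
    """
    if sino.n_views < 8:
        raise ValueError("refusing to reconstruct from fewer than 8 views")
    if filter_name not in ("hann", "ramp"):
        raise ValueError("filter_name must be 'hann' or 'ramp'")
    size = output_size or sino.projections.shape[0]
    img = iradon(
        sino.projections,
        theta=sino.angles,
        filter_name=filter_name,
        circle=True,
        output_size=size,
        preserve_range=True,
    )
    return ChannelVolume(img, sino.pixel_size, channel="reconstruction")
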