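"""Cell-centroid detection in stained slices.

The detector follows the simple recipe used for density mapping of stained
cells: blur with a Gaussian, keep pixels that are both above an intensity
threshold and at the top of their local neighborhood (a rank filter), group
the surviving pixels into 8-connected components, and report the mean pixel
location of each component as one cell.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .types import CellPoints, ChannelVolume

__all__ = ["detect_cells"]

log = logging.getLogger(__name__)


def detect_cells(
    image: ChannelVolume,
    sigma: float,
    intensity_threshold: float,
    rank_radius: int = 5,
    rank_percentile: float = 99.0,
    threshold_is_quantile: bool = False,
    slice_id: str = "0",
) -> CellPoints:
    """Detect cell centroids in one 2D slice.

    Parameters
    ----------
    sigma:
        Gaussian blur width in mm.
    intensity_threshold:
        Absolute intensity (in blurred-image units) or, with
        ``threshold_is_quantile``, a quantile in [0, 1) of the blurred image.
    rank_radius, rank_percentile:
        A pixel is kept only if the blurred value is >= the
        ``rank_percentile``-th percentile of its disk neighborhood of radius
        ``rank_radius`` pixels.

    Candidate pixels satisfying both conditions are clustered 8-connected;
    each cluster becomes one point at the unweighted mean pixel location,
    converted to mm (x = col * pixel_size, y = row * pixel_size). Clusters
    touching the image border are kept and flagged in ``border_flags``.
    A threshold above the image maximum returns an empty result.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = image.data if image.data.ndim == 2 else image.data[0]
    sigma_px = sigma / image.pixel_size
    blurred = ndimage.gaussian_filter(img, sigma_px)

    if threshold_is_quantile:
        if not 0 <= intensity_threshold < 1:
            raise ValueError("quantile threshold must be in [0, 1)")
        thr = float(np.quantile(blurred, intensity_threshold))
    else:
        thr = float(intensity_threshold)

    params = {
        "sigma_mm": sigma,
        "intensity_threshold": thr,
        "rank_radius_px": rank_radius,
        "rank_percentile": rank_percentile,
    }
    if thr > blurred.max():
        log.info("intensity threshold %.4g above image max; no detections", thr)
        return CellPoints(np.empty(0), np.empty(0), slice_id, params,
                          border_flags=np.empty(0, dtype=bool))

    footprint = disk(rank_radius)
    local_rank = ndimage.percentile_filter(
        blurred, rank_percentile, footprint=footprint, mode="nearest"
    )
    candidates = (blurred >= thr) & (blurred >= local_rank)

    labels, n = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return CellPoints(np.empty(0), np.empty(0), slice_id, params,
                          border_flags=np.empty(0, dtype=bool))
    centroids = ndimage.center_of_mass(candidates, labels, index=np.arange(1, n + 1))
    rows = np.array([c[0] for c in centroids])
    cols = np.array([c[1] for c in centroids])

    border = np.zeros((n,), dtype=bool)
    edge_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border[edge_labels[edge_labels > 0] - 1] = True

    return CellPoints(
        x=cols * image.pixel_size,
        y=rows * image.pixel_size,
        slice_id=slice_id,
        detection_params=params,
        border_flags=border,
    )
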