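"""Image corrections applied before display and quantification.

Three procedures:

1. **Non-uniformity (bias) correction** — a smooth multiplicative intensity
   field, such as the edge brightening of tomographic autofluorescence
   images, is estimated by a low-order polynomial fit to log intensity and
   divided out. This is a deliberately simple log-domain surrogate for
   full histogram-sharpening bias correction: the field it targets is
   smooth and low-order, and the correction is applied before display.
2. **Autofluorescence background subtraction** — the autofluorescence
   channel bleeds into the stain channel at an unknown scale; the scale is
   estimated by (robust) linear regression of the stain on the
   autofluorescence over background pixels, then the scaled channel is
   subtracted.
3. **Punctate-artifact removal** — isolated high-intensity pixels (e.g.
   unreacted antibody after incomplete washing) are found by high-pass
   filtering, normalizing to a local noise scale, and thresholding; the
   high-pass value is subtracted only at flagged pixels.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .types import BiasField, ChannelVolume, PunctateMask

__all__ = [
    "estimate_bias",
    "correct_bias",
    "estimate_background_scale",
    "subtract_background",
    "high_pass",
    "detect_punctate",
    "remove_punctate",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# bias field


def _poly_design(shape: tuple[int, int], order: int) -> np.ndarray:
    """Separable polynomial basis u^i v^j, i,j <= order, on [-1,1]^2."""
    h, w = shape
    u = np.linspace(-1.0, 1.0, h)[:, None] * np.ones((1, w))
    v = np.ones((h, 1)) * np.linspace(-1.0, 1.0, w)[None, :]
    cols = [
        (u**i * v**j).ravel() for i in range(order + 1) for j in range(order + 1)
    ]
    return np.column_stack(cols)


def estimate_bias(
    image: ChannelVolume,
    mask: np.ndarray | None = None,
    order: int = 3,
) -> BiasField:
    """Estimate a smooth multiplicative non-uniformity field.

    Fits a separable polynomial (default order 3 per axis) to the log of the
    intensities inside ``mask`` by least squares, exponentiates the fitted
    surface and normalizes it to spatial mean 1. The corrected image is
    ``image / bias`` (see :func:`correct_bias`).

    Raises if the mask covers less than 5% of pixels or the image is not
    strictly positive on the mask (add an offset before calling in that
    case).
    """
    img = image.data
    if img.ndim != 2:
        raise ValueError("bias estimation operates on 2D slices")
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 0.05 * mask.size:
        raise ValueError("mask must cover at least 5% of pixels")
    if np.any(img[mask] <= 0):
        raise ValueError(
            "image must be strictly positive on the mask; "
            "add a positive offset to the intensities before bias estimation"
        )
    design = _poly_design(img.shape, order)
    coef, *_ = np.linalg.lstsq(design[mask.ravel()], np.log(img[mask]), rcond=None)
    surface = design @ coef
    bias = np.exp(surface - surface.mean()).reshape(img.shape)
    bias /= bias.mean()
    return BiasField(values=bias, order=order)


def correct_bias(image: ChannelVolume, bias: BiasField) -> ChannelVolume:
    """Divide out an estimated bias field."""
    return ChannelVolume(
        image.data / bias.values,
        image.pixel_size,
        channel=image.channel,
        incubation_time=image.incubation_time,
        meta={**image.meta, "bias_order": bias.order},
    )


# ---------------------------------------------------------------------------
# background subtraction


def estimate_background_scale(
    stain: ChannelVolume,
    auto: ChannelVolume,
    exclude: np.ndarray | None = None,
    foreground_quantile: float = 0.95,
    trim_sd: float = 3.0,
    max_iter: int = 5,
) -> float:
    """Scale matching the autofluorescence channel to the stain background.

    Least-squares slope of stain on autofluorescence restricted to
    background pixels, with iterative trimming of outliers (residual beyond
    ``trim_sd`` standard deviations, at most ``max_iter`` rounds) so that
    stained foreground does not bias the slope. ``exclude`` marks known
    foreground; by default pixels above the ``foreground_quantile`` of the
    stain channel are excluded. An intercept is included in the fit; only
    the slope is returned.
    """
    if stain.data.shape != auto.data.shape:
        raise ValueError("channels must share a grid")
    s = stain.data.ravel()
    a = auto.data.ravel()
    if exclude is None:
        keep = s <= np.quantile(s, foreground_quantile)
    else:
        keep = ~np.asarray(exclude, dtype=bool).ravel()
    if a[keep].std() == 0:
        raise ValueError("autofluorescence channel has zero variance on background")

    slope = 0.0
    for _ in range(max_iter):
        design = np.column_stack([a[keep], np.ones(keep.sum())])
        (slope, intercept), *_ = np.linalg.lstsq(design, s[keep], rcond=None)
        resid = s - (slope * a + intercept)
        sd = resid[keep].std()
        if sd == 0:
            break
        new_keep = keep & (np.abs(resid) <= trim_sd * sd)
        if new_keep.sum() == keep.sum() or new_keep.sum() < 2:
            break
        keep = new_keep
        if a[keep].std() == 0:
            raise ValueError("background regressor degenerated during trimming")
    return float(slope)


def subtract_background(
    stain: ChannelVolume,
    auto: ChannelVolume,
    scale: float,
) -> tuple[ChannelVolume, float]:
    """Subtract the scaled autofluorescence channel, clipping at zero.

    Returns the corrected channel and the fraction of pixels clipped.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    if stain.data.shape != auto.data.shape:
        raise ValueError("channels must share a grid")
    raw = stain.data - scale * auto.data
    clipped = raw < 0
    corrected = np.where(clipped, 0.0, raw)
    frac = float(clipped.mean())
    out = ChannelVolume(
        corrected,
        stain.pixel_size,
        channel=stain.channel,
        incubation_time=stain.incubation_time,
        meta={**stain.meta, "background_scale": scale, "clipping_fraction": frac},
    )
    return out, frac


# ---------------------------------------------------------------------------
# punctate artifacts


def high_pass(image: np.ndarray | ChannelVolume, hp_size: int = 3) -> np.ndarray:
    """High-pass by subtracting a median filter (robust to impulses).

    The center pixel is excluded from the median window, so the residual at
    a pixel is measured against its neighborhood alone. This keeps the
    residual of pure noise near-Gaussian relative to its robust scale
    (center-included medians correlate with the pixel itself and produce
    heavy-tailed z-scores) and means an impulse is restored exactly to its
    neighborhood median when the high-pass is subtracted.
    """
    img = image.data if isinstance(image, ChannelVolume) else np.asarray(image, float)
    if hp_size < 3 or hp_size % 2 == 0:
        raise ValueError("hp_size must be odd and >= 3")
    footprint = np.ones((hp_size, hp_size), dtype=bool)
    footprint[hp_size // 2, hp_size // 2] = False
    return img - ndimage.median_filter(img, footprint=footprint, mode="nearest")


def detect_punctate(
    image: ChannelVolume,
    hp_size: int = 3,
    sd_window: int = 15,
    threshold_sd: float = 5.0,
    max_component_size: int = 2,
) -> PunctateMask:
    """Flag isolated high-intensity pixels.

    The high-pass residual (image minus median filter) is divided by a local
    robust SD — 1.4826 x the local median absolute residual over a
    ``sd_window`` window — and thresholded at ``threshold_sd``. The robust
    local scale is used so that a spike cannot inflate its own denominator:
    a single pixel cannot move the median of a 15x15 window. Flagged
    connected components larger than ``max_component_size`` pixels are
    dropped as structure rather than artifact. Only positive excursions are
    flagged (the artifacts are high-intensity).

    Zero local-scale regions are floored at 1e-3 of the global robust SD
    (logged); a perfectly flat image yields an empty mask.
    """
    img = image.data
    if img.ndim != 2:
        raise ValueError("punctate detection operates on 2D slices")
    if sd_window < 3 or sd_window % 2 == 0:
        raise ValueError("sd_window must be odd and >= 3")

    hp = high_pass(img, hp_size)
    abs_hp = np.abs(hp)
    global_scale = 1.4826 * np.median(abs_hp)
    if global_scale == 0:
        # also covers constant images, whose high-pass is identically zero
        global_scale = 1.4826 * abs_hp.mean()
    if global_scale == 0:
        flags = np.zeros(img.shape, dtype=bool)
        return PunctateMask(flags, hp_size, sd_window, threshold_sd, max_component_size)

    local_scale = 1.4826 * ndimage.median_filter(abs_hp, size=sd_window, mode="nearest")
    floor = global_scale * 1e-3
    n_floored = int((local_scale < floor).sum())
    if n_floored:
        log.debug("flooring local SD at %d pixels", n_floored)
    local_scale = np.maximum(local_scale, floor)

    z = hp / local_scale
    flags = z > threshold_sd

    labels, n = ndimage.label(flags, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = ndimage.sum_labels(flags, labels, index=np.arange(1, n + 1))
        too_big = np.flatnonzero(sizes > max_component_size) + 1
        if len(too_big):
            flags &= ~np.isin(labels, too_big)
    return PunctateMask(flags, hp_size, sd_window, threshold_sd, max_component_size)


def remove_punctate(
    image: ChannelVolume,
    mask: PunctateMask,
    highpass: np.ndarray | None = None,
) -> ChannelVolume:
    """Subtract the high-pass value at flagged pixels only.

    Pixels outside the mask are preserved bit-exactly. If ``highpass`` is
    not supplied it is recomputed with the mask's ``hp_size``.
    """
    img = image.data
    if mask.flags.shape != img.shape:
        raise ValueError("mask and image must share a grid")
    if highpass is None:
        highpass = high_pass(img, mask.hp_size)
    if highpass.shape != img.shape:
        raise ValueError("highpass and image must share a grid")
    out = img.copy()
    out[mask.flags] = img[mask.flags] - highpass[mask.flags]
    return ChannelVolume(
        out,
        image.pixel_size,
        channel=image.channel,
        incubation_time=image.incubation_time,
        meta={**image.meta, "punctate_removed": mask.count},
    )
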