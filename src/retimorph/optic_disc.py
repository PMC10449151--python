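"""Optic disc localisation.

The optic disc is the brightest large structure in a healthy macular-centred
fundus image, but slow illumination gradients can place the raw intensity
maximum elsewhere.  Localisation therefore applies shade correction —
subtraction of a large-scale background estimate — followed by the position
of maximum smoothed intensity within a constrained search region (the image
minus a border margin and a central fovea-zone exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["DiscConfig", "DiscLocation", "shade_correct", "locate_disc"]


@dataclass(frozen=True)
class DiscConfig:
    border_frac: float = 0.05       # excluded margin on every side
    fovea_exclusion_frac: float = 0.15  # radius around image centre, of height
    radius_frac: float = 0.08       # disc radius estimate, fraction of height
    background_scale_frac: float = 0.25  # shade-correction scale, of min dim


@dataclass(frozen=True)
class DiscLocation:
    centre: tuple[float, float]   # (row, col)
    radius_estimate: float        # px
    confidence: float             # max shade-corrected intensity


def shade_correct(image: np.ndarray, background_scale: float) -> np.ndarray:
    """Subtract a Gaussian background estimate at ``background_scale`` px.

    Removes slow illumination gradients; a constant image maps to zeros.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("shade_correct expects a single-channel image")
    if background_scale >= min(img.shape):
        raise ValueError("background_scale must be smaller than the image")
    if background_scale <= 0:
        raise ValueError("background_scale must be positive")
    return img - ndimage.gaussian_filter(img, background_scale, mode="reflect")


def locate_disc(image: np.ndarray, config: DiscConfig | None = None,
                fovea_centre: tuple[float, float] | None = None) -> DiscLocation:
    """Brightest point of the smoothed, shade-corrected image in-region.

    The search region excludes a ``border_frac`` margin and a disc around the
    fovea (given, or taken as the image centre for macular-centred images).
    No left/right prior is imposed — the disc side depends on the eye.
    """
    cfg = config or DiscConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., 1]
    h, w = img.shape
    radius = cfg.radius_frac * h
    corrected = shade_correct(img, cfg.background_scale_frac * min(h, w))
    smooth = ndimage.gaussian_filter(corrected, radius / 4.0)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    region = np.ones((h, w), dtype=bool)
    mr, mc = int(round(cfg.border_frac * h)), int(round(cfg.border_frac * w))
    if mr > 0:
        region[:mr] = region[-mr:] = False
    if mc > 0:
        region[:, :mc] = region[:, -mc:] = False
    fc = fovea_centre if fovea_centre is not None else (h / 2.0, w / 2.0)
    excl = cfg.fovea_exclusion_frac * h
    region &= np.hypot(rr - fc[0], cc - fc[1]) > excl
    if not region.any():
        raise ValueError("search region is empty")
    masked = np.where(region, smooth, -np.inf)
    idx = np.unravel_index(np.argmax(masked), masked.shape)
    return DiscLocation(centre=(float(idx[0]), float(idx[1])),
                        radius_estimate=float(radius),
                        confidence=float(masked[idx]))
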