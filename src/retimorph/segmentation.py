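"""Unsupervised vessel segmentation.

A multi-scale line detector scores each pixel by the contrast between the
best-fitting oriented line through it and its local surround, maximised over
line lengths and orientations; hysteresis thresholding realised as
morphological reconstruction turns the response into a binary vessel map.
Pre-processing suppresses bright pixels (optic disc, reflections) so they
cannot masquerade as line structure; post-processing removes the fovea and
small spurious objects.

The detector is contrast-based (a difference of local means), so the response
— and hence the segmentation — is invariant to adding a constant to the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, transform

__all__ = [
    "LineDetectorConfig",
    "VesselMask",
    "line_response",
    "hysteresis_reconstruct",
    "preprocess_bright",
    "postprocess_mask",
    "estimate_fovea",
    "segment_vessels",
]


@dataclass(frozen=True)
class LineDetectorConfig:
    """Multi-scale line detector parameters.

    ``line_lengths`` are odd lengths (px) of the oriented averaging lines,
    ascending; the surround ``window_size`` must cover the longest line.
    Hysteresis thresholds are set as percentiles of the response map.
    """

    line_lengths: tuple[int, ...] = (5, 9, 15)
    n_orientations: int = 12
    window_size: int = 15
    channel: str = "green"           # "green" | "luminance"
    low_percentile: float = 90.0
    high_percentile: float = 96.0
    low_floor: float = 0.012         # absolute response floors: percentile
    high_floor: float = 0.020        # thresholds never drop below vessel-level
                                     # contrast, so degraded images collapse
    bright_percentile: float = 95.0  # pre-processing cutoff
    min_object_area: int = 64        # px^2, post-processing
    fovea_radius_frac: float = 0.10  # of image height, exclusion disc

    def validate(self) -> None:
        if list(self.line_lengths) != sorted(self.line_lengths):
            raise ValueError("line_lengths must be ascending")
        if any(l % 2 == 0 or l < 1 for l in self.line_lengths):
            raise ValueError("line_lengths must be odd and positive")
        if self.n_orientations < 8:
            raise ValueError("n_orientations must be >= 8")
        if self.window_size < max(self.line_lengths):
            raise ValueError("window_size must cover the longest line")
        if not self.low_percentile < self.high_percentile:
            raise ValueError("low_percentile must be below high_percentile")


@dataclass
class VesselMask:
    """Binary vessel map with provenance flags."""

    data: np.ndarray  # bool (H, W)
    preprocessed: bool = False
    postprocessed: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)


def _grey(image: np.ndarray, channel: str) -> np.ndarray:
    if image.ndim == 2:
        return np.asarray(image, dtype=float)
    if channel == "green":
        return np.asarray(image[..., 1], dtype=float)
    return np.asarray(image, dtype=float) @ np.array([0.2126, 0.7152, 0.0722])


def line_response(image: np.ndarray, config: LineDetectorConfig | None = None,
                  return_orientation: bool = False):
    """Multi-scale oriented line-contrast response.

    Per pixel: ``max`` over orientations and line lengths of
    ``mean(window) - mean(line)`` (equivalently the line mean on the inverted
    image minus its surround), clipped at zero — large on dark curvilinear
    structures.  Optionally also returns the argmax orientation index.
    """
    config = config or LineDetectorConfig()
    config.validate()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("line_response expects a single-channel image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must contain finite values")
    if min(img.shape) < config.window_size:
        raise ValueError("image smaller than the detector window")

    win_mean = ndimage.uniform_filter(img, size=config.window_size, mode="reflect")
    lmax = max(config.line_lengths)
    half = lmax // 2
    padded = np.pad(img, half, mode="reflect")
    h, w = img.shape
    response = np.zeros_like(img)
    best_orient = np.zeros(img.shape, dtype=np.int16)
    # offsets ordered by |k| so prefix sums give nested (collinear) lengths
    ks = np.arange(-half, half + 1)
    order = np.argsort(np.abs(ks), kind="stable")
    ks = ks[order]
    cuts = {l: l for l in config.line_lengths}
    for oi in range(config.n_orientations):
        theta = oi * np.pi / config.n_orientations
        dy = np.rint(ks * np.sin(theta)).astype(int)
        dx = np.rint(ks * np.cos(theta)).astype(int)
        acc = np.zeros_like(img)
        for count, (ddy, ddx) in enumerate(zip(dy, dx), start=1):
            acc += padded[half + ddy: half + ddy + h, half + ddx: half + ddx + w]
            if count in cuts:
                resp = win_mean - acc / count
                upd = resp > response
                response[upd] = resp[upd]
                best_orient[upd] = oi
    np.clip(response, 0.0, None, out=response)
    response[response < 1e-12] = 0.0   # float accumulation dust on flat fields
    if return_orientation:
        return response, best_orient
    return response


def hysteresis_reconstruct(response: np.ndarray, low: float, high: float) -> VesselMask:
    """Dual-threshold segmentation by morphological reconstruction.

    Keeps every connected component of ``{response >= low}`` that contains at
    least one seed pixel of ``{response >= high}``.
    """
    if not low < high:
        raise ValueError("low threshold must be strictly below high")
    resp = np.asarray(response, dtype=float)
    # skimage uses (low, high) exclusive/inclusive semantics matching >= after
    # a tiny epsilon shift; implement explicitly for exact >= semantics.
    low_mask = resp >= low
    seeds = resp >= high
    lbl, n = ndimage.label(low_mask, structure=np.ones((3, 3)))
    if n == 0 or not seeds.any():
        return VesselMask(np.zeros_like(low_mask))
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(lbl[seeds])] = True
    keep[0] = False
    return VesselMask(keep[lbl])


def preprocess_bright(image: np.ndarray, percentile: float = 95.0) -> np.ndarray:
    """Replace pixels above an intensity percentile with a local background.

    The background is a normalised (masked) Gaussian blur computed from the
    non-bright pixels only, so a saturated optic disc or flash artefact is
    flattened into its surround and cannot produce line responses.
    ``percentile=100`` is the identity.
    """
    if not 50 < percentile <= 100:
        raise ValueError("percentile must be in (50, 100]")
    img = np.asarray(image, dtype=float)
    if percentile == 100:
        return img.copy()
    cutoff = np.percentile(img, percentile)
    bright = img > cutoff
    if not bright.any():
        return img.copy()
    sigma = max(img.shape) / 24.0
    keep = (~bright).astype(float)
    num = ndimage.gaussian_filter(img * keep, sigma)
    den = ndimage.gaussian_filter(keep, sigma)
    background = num / np.maximum(den, 1e-12)
    out = img.copy()
    out[bright] = background[bright]
    return out


def estimate_fovea(image: np.ndarray, channel: str = "green") -> tuple[float, float]:
    """Darkest large-scale minimum in the central third of a macular image."""
    grey = _grey(image, channel)
    h, w = grey.shape
    smooth = ndimage.gaussian_filter(grey, min(h, w) / 24.0)
    r0, r1 = h // 3, 2 * h // 3
    c0, c1 = w // 3, 2 * w // 3
    idx = np.argmin(smooth[r0:r1, c0:c1])
    rr, cc = np.unravel_index(idx, (r1 - r0, c1 - c0))
    return (float(rr + r0), float(cc + c0))


def postprocess_mask(mask: VesselMask, min_object_area: int = 64,
                     fovea_centre: tuple[float, float] | None = None,
                     fovea_radius: float = 0.0) -> VesselMask:
    """Remove small spurious objects and the fovea exclusion disc."""
    if min_object_area < 0:
        raise ValueError("min_object_area must be >= 0")
    data = mask.data.copy()
    if min_object_area > 0:
        data = morphology.remove_small_objects(data, max_size=min_object_area - 1)
    if fovea_centre is not None and fovea_radius > 0:
        rr, cc = np.mgrid[0:data.shape[0], 0:data.shape[1]].astype(float)
        inside = np.hypot(rr - fovea_centre[0], cc - fovea_centre[1]) <= fovea_radius
        data &= ~inside
    return VesselMask(data, preprocessed=mask.preprocessed, postprocessed=True)


def segment_vessels(image: np.ndarray, config: LineDetectorConfig | None = None,
                    pre: bool = True, post: bool = True,
                    fovea_centre: tuple[float, float] | None = None,
                    working_long_side: int | None = None) -> VesselMask:
    """Full segmentation: preprocess -> line response -> hysteresis -> postprocess.

    ``image`` may be RGB (H, W, 3) or single-channel; ``working_long_side``
    optionally downscales before detection (mask upscaled back by
    nearest-neighbour).  Hysteresis thresholds are taken as percentiles of the
    response map.  A flat image yields an empty mask.
    """
    config = config or LineDetectorConfig()
    config.validate()
    grey = _grey(np.asarray(image), config.channel)
    orig_shape = grey.shape
    scale = 1.0
    if working_long_side is not None and max(grey.shape) > working_long_side:
        scale = working_long_side / max(grey.shape)
        new_shape = (round(grey.shape[0] * scale), round(grey.shape[1] * scale))
        grey = transform.resize(grey, new_shape, order=1, anti_aliasing=True)
    if pre:
        grey = preprocess_bright(grey, config.bright_percentile)
    response = line_response(grey, config)
    if response.max() <= 0:
        mask = VesselMask(np.zeros(grey.shape, dtype=bool), preprocessed=pre)
    else:
        low = max(np.percentile(response, config.low_percentile), config.low_floor)
        high = max(np.percentile(response, config.high_percentile), config.high_floor)
        if not low < high:
            mask = VesselMask(response >= high, preprocessed=pre)
        else:
            mask = hysteresis_reconstruct(response, low, high)
            mask.preprocessed = pre
    if post:
        fc = fovea_centre
        if fc is None:
            fc = estimate_fovea(grey if grey.ndim == 2 else image, config.channel)
        elif scale != 1.0:
            fc = (fc[0] * scale, fc[1] * scale)
        mask = postprocess_mask(mask, config.min_object_area, fc,
                                config.fovea_radius_frac * grey.shape[0])
    if mask.data.shape != orig_shape:
        up = transform.resize(mask.data.astype(float), orig_shape, order=0,
                              anti_aliasing=False) > 0.5
        mask = VesselMask(up, preprocessed=mask.preprocessed,
                          postprocessed=mask.postprocessed)
    return mask
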