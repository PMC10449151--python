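"""Synthetic fundus images with exact vascular ground truth.

Emulates the population of macular-centred, 45-degree field-of-view colour
fundus photographs used to validate retinal vasculometry software: a bright
optic disc, a dark fovea, and a branching vessel tree drawn as dark
curvilinear troughs on a brighter background.  Every image carries exact
bookkeeping (binary vessel mask, per-point centreline widths, arteriole /
venule labels, disc and fovea positions, a quality label), so each pipeline
stage can be scored against ground truth without any external data.

Three vessel-profile regimes are supported, mirroring the strata used in
width-measurement validation studies: ``normal`` (plain trough),
``central_reflex`` (a bright specular ridge along the vessel axis) and
``low_contrast`` (reduced amplitude plus uneven illumination).  Quality
degradations (``blur``, ``uneven_illumination``, ``occlusion``) are applied
last; extreme blur and large occlusions define the *inadequate* quality class.

The cross-section of a vessel of nominal width ``w`` is a baseline-subtracted
Gaussian trough with scale ``s = w/2``::

    offset(d) = -A * (exp(-d^2 / (2 s^2)) - exp(-2)) / (1 - exp(-2)),  |d| <= 2s
    offset(d) = 0,                                                     |d| >  2s

The baseline subtraction makes the profile exactly zero at ``|d| = w`` while
leaving the second derivative unchanged, so the zero-crossings of the second
derivative sit exactly at ``d = ±s`` and the edge-to-edge distance measured by
the width module equals the nominal width — a closed-form oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "CentrelinePoint",
    "render_vessel_profile",
    "generate_retina",
    "straight_vessel_image",
]

ProfileRegime = Literal["normal", "central_reflex", "low_contrast"]
Degradation = Literal["none", "blur", "uneven_illumination", "occlusion"]

# Rendering constants (intensities on a [0, 1] scale).
BACKGROUND_LEVEL = 0.62
VIGNETTE_STRENGTH = 0.12
DISC_BRIGHTNESS = 0.30
FOVEA_DEPTH = 0.13
VENULE_AMPLITUDE = 0.36      # venules appear darker than arterioles
ARTERIOLE_AMPLITUDE = 0.25
REFLEX_RELATIVE_AMPLITUDE = 0.35   # bright axial ridge, fraction of trough depth
REFLEX_SIGMA_FRACTION_A = 1 / 4.0  # reflex is wider in arterioles ...
REFLEX_SIGMA_FRACTION_V = 1 / 6.0  # ... than in venules of comparable size
LOW_CONTRAST_FACTOR = 0.45
PIXEL_NOISE_SD = 0.010
BLUR_SIGMA_FRACTION = 1 / 32.0     # of image height; destroys vessel detail
OCCLUSION_AREA_FRACTION = 0.60
GREEN_WEIGHTS = (0.92, 1.0, 0.55)  # R, G, B multipliers of the grey rendering

_SUPPORT = 2.0          # profile support in units of sigma
_BASE = np.exp(-2.0)    # profile value removed by baseline subtraction


class InvalidSpecError(ValueError):
    """Raised when a :class:`SyntheticSpec` violates its invariants."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic fundus image.

    Geometric defaults scale linearly with image size via :meth:`default`.
    """

    image_size: tuple[int, int] = (512, 512)      # (height, width)
    disc_centre: tuple[float, float] = (256.0, 118.0)  # (row, col)
    disc_radius: float = 40.0
    fovea_centre: tuple[float, float] = (256.0, 310.0)
    tree_depth: int = 4
    root_width: float = 18.0
    width_decay: float = 0.8
    profile_regime: ProfileRegime = "normal"
    degradation: Degradation = "none"
    seed: int = 0
    swap_av_intensity: bool = False  # render arterioles dark / venules bright

    @classmethod
    def default(cls, image_size: tuple[int, int] = (512, 512), **overrides) -> "SyntheticSpec":
        """A spec with geometry scaled to ``image_size`` (from the 512 px base)."""
        h, w = image_size
        s = min(h, w) / 512.0
        base = cls(
            image_size=(h, w),
            disc_centre=(h / 2.0, 0.23 * w),
            disc_radius=40.0 * s,
            fovea_centre=(h / 2.0, 0.61 * w),
            root_width=18.0 * s,
        )
        return replace(base, **overrides)

    def validate(self) -> None:
        h, w = self.image_size
        if h < 64 or w < 64:
            raise InvalidSpecError("image_size must be at least 64x64")
        if self.disc_radius <= 0:
            raise InvalidSpecError("disc_radius must be positive")
        if self.root_width < 2:
            raise InvalidSpecError("root_width must be >= 2 px")
        if self.root_width >= self.disc_radius:
            raise InvalidSpecError("root_width must be smaller than disc_radius")
        for name, (r, c) in (("disc_centre", self.disc_centre), ("fovea_centre", self.fovea_centre)):
            if not (0 <= r < h and 0 <= c < w):
                raise InvalidSpecError(f"{name} lies outside the image bounds")
        if self.tree_depth < 0:
            raise InvalidSpecError("tree_depth must be >= 0")
        if not (0 < self.width_decay <= 1):
            raise InvalidSpecError("width_decay must be in (0, 1]")


@dataclass(frozen=True)
class CentrelinePoint:
    row: float
    col: float
    width: float
    av_label: str       # "A" or "V"
    segment_id: int


@dataclass
class GroundTruth:
    """Exact bookkeeping for one synthetic image."""

    vessel_mask: np.ndarray                 # bool (H, W)
    centreline_points: list[CentrelinePoint]
    disc_centre: tuple[float, float]
    disc_radius: float
    fovea_centre: tuple[float, float]
    fovea_radius: float
    quality_label: str                      # "adequate" | "inadequate"
    regime: str
    spec: SyntheticSpec = field(repr=False, default=None)

    def centreline_array(self) -> np.ndarray:
        """(n, 2) float array of centreline (row, col) coordinates."""
        return np.array([(p.row, p.col) for p in self.centreline_points], dtype=float)


# ---------------------------------------------------------------------------
# Cross-section profile
# ---------------------------------------------------------------------------

def render_vessel_profile(distance, width, regime: ProfileRegime = "normal",
                          av_label: str = "V", amplitude: float | None = None):
    """Intensity offset at signed ``distance`` px from the centreline.

    Even in ``distance``; exactly zero for ``|distance| >= width`` (compact
    support at twice the trough scale ``s = width/2``).  ``central_reflex``
    adds a bright narrow Gaussian ridge on the axis; ``low_contrast`` scales
    the trough depth by :data:`LOW_CONTRAST_FACTOR`.
    """
    width = float(width)
    if width <= 0:
        raise ValueError("width must be positive")
    d = np.asarray(distance, dtype=float)
    s = width / 2.0
    if amplitude is None:
        amplitude = VENULE_AMPLITUDE if av_label == "V" else ARTERIOLE_AMPLITUDE
    if regime == "low_contrast":
        amplitude = amplitude * LOW_CONTRAST_FACTOR
    core = np.exp(-0.5 * (d / s) ** 2)
    trough = -amplitude * np.clip((core - _BASE) / (1.0 - _BASE), 0.0, None)
    trough = np.where(np.abs(d) <= _SUPPORT * s, trough, 0.0)
    if regime == "central_reflex":
        frac = REFLEX_SIGMA_FRACTION_A if av_label == "A" else REFLEX_SIGMA_FRACTION_V
        s_r = max(frac * s, 0.6)
        ridge = REFLEX_RELATIVE_AMPLITUDE * amplitude * np.exp(-0.5 * (d / s_r) ** 2)
        ridge = np.where(np.abs(d) <= _SUPPORT * s, ridge, 0.0)
        trough = trough + ridge
    return trough if trough.shape else float(trough)


# ---------------------------------------------------------------------------
# Vessel tree growth
# ---------------------------------------------------------------------------

@dataclass
class _Branch:
    points: np.ndarray   # (n, 2) float, ~1 px spacing
    width: float
    av_label: str
    segment_id: int


def _grow_branch(rng, start, heading, length, curvature_sd, bounds):
    h, w = bounds
    pts = [np.asarray(start, dtype=float)]
    theta = float(heading)
    bias = rng.normal(0.0, 0.004)
    for _ in range(int(length)):
        theta += bias + rng.normal(0.0, curvature_sd)
        nxt = pts[-1] + np.array([np.sin(theta), np.cos(theta)])
        if not (1 <= nxt[0] < h - 1 and 1 <= nxt[1] < w - 1):
            break
        pts.append(nxt)
    return np.array(pts), theta


def _grow_tree(spec: SyntheticSpec, rng) -> list[_Branch]:
    """Recursive bifurcating tree from the optic disc edge.

    Arteriole and venule trees are grown with identical geometry statistics
    (same root width, lengths and branching angles) so that the two classes
    differ only in rendered intensity, not calibre.
    """
    h, w = spec.image_size
    scale = min(h, w) / 512.0
    branches: list[_Branch] = []
    if spec.tree_depth == 0:
        return branches
    seg_counter = 0
    dc = np.asarray(spec.disc_centre, dtype=float)
    towards_fovea = np.arctan2(spec.fovea_centre[0] - dc[0], spec.fovea_centre[1] - dc[1])
    # Four arcades leaving the disc: superior/inferior x {A, V}.
    root_headings = towards_fovea + np.array([0.9, 0.55, -0.55, -0.9]) * np.pi / 2
    labels = ["A", "V", "V", "A"]
    stack = []
    for heading, label in zip(root_headings, labels):
        start = dc + spec.disc_radius * 0.9 * np.array([np.sin(heading), np.cos(heading)])
        stack.append((start, heading + rng.normal(0, 0.1), spec.root_width, label, 1))
    base_len = 50.0 * scale
    while stack:
        start, heading, width, label, depth = stack.pop()
        length = base_len * rng.uniform(0.7, 1.15) * (0.92 ** (depth - 1))
        pts, end_theta = _grow_branch(rng, start, heading, length,
                                      curvature_sd=0.035, bounds=(h, w))
        if len(pts) < 6:
            continue
        branches.append(_Branch(pts, max(width, 2.0), label, seg_counter))
        seg_counter += 1
        if depth < spec.tree_depth:
            child_w = max(width * spec.width_decay, 2.0)
            split = np.deg2rad(rng.uniform(20.0, 36.0))
            for sgn in (-1.0, 1.0):
                stack.append((pts[-1], end_theta + sgn * split, child_w, label, depth + 1))
    return branches


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------

def _rasterise(branches: list[_Branch], shape, regime: str, swap: bool):
    """Per-pixel vessel intensity offset and ground-truth fields.

    Centreline samples are stamped on a 2x supersampled grid; a Euclidean
    distance transform assigns every pixel its distance to (and identity of)
    the nearest centreline sample, from which the analytic cross-section
    profile is evaluated.  Supersampling keeps the quantisation of the
    distance field below 0.25 px.
    """
    h, w = shape
    f = 2  # supersampling factor
    stamp = np.full((h * f, w * f), -1, dtype=np.int32)
    samples = []
    for br in branches:
        # ~0.5 px spacing for a smooth stamp
        n = max(len(br.points) * 2 - 1, 1)
        t = np.linspace(0, len(br.points) - 1, n)
        rows = np.interp(t, np.arange(len(br.points)), br.points[:, 0])
        cols = np.interp(t, np.arange(len(br.points)), br.points[:, 1])
        for r, c in zip(rows, cols):
            rr, cc = int(round(r * f)), int(round(c * f))
            if 0 <= rr < h * f and 0 <= cc < w * f:
                samples.append((br.width, 1.0 if br.av_label == "A" else 0.0))
                stamp[rr, cc] = len(samples) - 1
    offset = np.zeros((h, w), dtype=float)
    mask = np.zeros((h, w), dtype=bool)
    if not samples:
        return offset, mask
    widths = np.array([s[0] for s in samples])
    is_art = np.array([s[1] for s in samples]) > 0.5
    dist2, (ir, ic) = ndimage.distance_transform_edt(stamp < 0, return_indices=True)
    nearest = stamp[ir, ic]
    d = (dist2 / f)[::f, ::f]
    nearest = nearest[::f, ::f]
    wfield = widths[nearest]
    afield = is_art[nearest]
    amp_a, amp_v = ARTERIOLE_AMPLITUDE, VENULE_AMPLITUDE
    if swap:
        amp_a, amp_v = amp_v, amp_a
    amp = np.where(afield, amp_a, amp_v)
    if regime == "low_contrast":
        amp = amp * LOW_CONTRAST_FACTOR
    s = wfield / 2.0
    inside = d <= _SUPPORT * s
    core = np.exp(-0.5 * (d / s) ** 2)
    offset = np.where(inside, -amp * np.clip((core - _BASE) / (1.0 - _BASE), 0, None), 0.0)
    if regime == "central_reflex":
        frac = np.where(afield, REFLEX_SIGMA_FRACTION_A, REFLEX_SIGMA_FRACTION_V)
        s_r = np.maximum(frac * s, 0.6)
        offset = offset + np.where(
            inside, REFLEX_RELATIVE_AMPLITUDE * amp * np.exp(-0.5 * (d / s_r) ** 2), 0.0)
    mask = d <= wfield / 2.0
    return offset, mask


def _background(spec: SyntheticSpec) -> np.ndarray:
    h, w = spec.image_size
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    centre = np.array([h / 2.0, w / 2.0])
    rnorm = np.hypot(rr - centre[0], cc - centre[1]) / (0.5 * np.hypot(h, w))
    img = BACKGROUND_LEVEL * (1.0 - VIGNETTE_STRENGTH * rnorm ** 2)
    # Bright optic disc: flat-topped super-Gaussian, the brightest structure.
    dr = np.hypot(rr - spec.disc_centre[0], cc - spec.disc_centre[1])
    img = img + DISC_BRIGHTNESS * np.exp(-((dr / spec.disc_radius) ** 4))
    # Dark fovea.
    fovea_radius = 1.1 * spec.disc_radius
    fr = np.hypot(rr - spec.fovea_centre[0], cc - spec.fovea_centre[1])
    img = img - FOVEA_DEPTH * np.exp(-0.5 * (fr / fovea_radius) ** 2)
    return img, fovea_radius


def _degrade(img: np.ndarray, spec: SyntheticSpec, rng) -> np.ndarray:
    h, w = img.shape
    if spec.degradation == "blur":
        img = ndimage.gaussian_filter(img, BLUR_SIGMA_FRACTION * h)
    elif spec.degradation == "uneven_illumination":
        ramp = np.linspace(-0.16, 0.16, w)[None, :] * rng.choice([-1.0, 1.0])
        img = img + ramp
    elif spec.degradation == "occlusion":
        radius = np.sqrt(OCCLUSION_AREA_FRACTION * h * w / np.pi)
        cy = rng.uniform(0.35 * h, 0.65 * h)
        cx = rng.uniform(0.35 * w, 0.65 * w)
        rr, cc = np.mgrid[0:h, 0:w].astype(float)
        blob = np.hypot(rr - cy, cc - cx) <= radius
        img = np.where(blob, 0.06, img)
    return img


def generate_retina(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic fundus image and its exact ground truth.

    Returns ``(image, truth)`` where ``image`` is an RGB float array in
    [0, 1] of shape ``(H, W, 3)``.  Deterministic for a fixed spec (the seed
    is part of the spec).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    grey, fovea_radius = _background(spec)
    if spec.profile_regime == "low_contrast":
        h, w = spec.image_size
        grey = grey + np.linspace(-0.10, 0.10, w)[None, :]
    branches = _grow_tree(spec, rng)
    offset, mask = _rasterise(branches, spec.image_size, spec.profile_regime,
                              spec.swap_av_intensity)
    grey = grey + offset
    grey = grey + rng.normal(0.0, PIXEL_NOISE_SD, size=grey.shape)
    grey = _degrade(grey, spec, rng)
    grey = np.clip(grey, 0.0, 1.0)
    img = np.clip(np.stack([grey * gw for gw in GREEN_WEIGHTS], axis=-1), 0.0, 1.0)

    points: list[CentrelinePoint] = []
    h, w = spec.image_size
    for br in branches:
        for r, c in br.points:
            ri, ci = int(round(r)), int(round(c))
            if 0 <= ri < h and 0 <= ci < w and mask[ri, ci]:
                points.append(CentrelinePoint(float(r), float(c), br.width,
                                              br.av_label, br.segment_id))
    quality = "inadequate" if spec.degradation in ("blur", "occlusion") else "adequate"
    truth = GroundTruth(
        vessel_mask=mask,
        centreline_points=points,
        disc_centre=spec.disc_centre,
        disc_radius=spec.disc_radius,
        fovea_centre=spec.fovea_centre,
        fovea_radius=fovea_radius,
        quality_label=quality,
        regime=spec.profile_regime,
        spec=spec,
    )
    return img, truth


def straight_vessel_image(shape, centre, angle, width,
                          regime: ProfileRegime = "normal", av_label: str = "V",
                          background: float = BACKGROUND_LEVEL,
                          noise_sd: float = 0.0, seed: int = 0):
    """A single straight vessel rendered from the exact analytic profile.

    The perpendicular distance to the infinite line through ``centre`` at
    ``angle`` (radians, tangent direction) is computed in closed form, so the
    rendered cross-section is exactly :func:`render_vessel_profile` — the
    fixture used by the width-measurement oracle tests.
    Returns ``(grey_image, distance_field)``.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    n = np.array([-np.cos(angle), np.sin(angle)])  # unit normal in (row, col)
    d = (rr - centre[0]) * n[0] + (cc - centre[1]) * n[1]
    img = background + render_vessel_profile(d, width, regime, av_label)
    if noise_sd > 0:
        img = img + np.random.default_rng(seed).normal(0, noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0), d


def generate_quality_cohort(n: int, seed: int, image_size: tuple[int, int] = (256, 256),
                            inadequate_fraction: float = 0.174):
    """Specs for a mixed-quality image cohort.

    The inadequate prevalence default (17.4%) matches the class balance of
    the manually labelled 1,000-image set used to train quality classifiers
    on real data.  Inadequate images are extreme blur or large occlusions;
    adequate images span the three profile regimes with occasional uneven
    illumination.  Returns a list of :class:`SyntheticSpec`.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        inadequate = rng.random() < inadequate_fraction
        if inadequate:
            deg = rng.choice(["blur", "occlusion"])
        else:
            deg = rng.choice(["none", "none", "uneven_illumination"])
        regime = rng.choice(["normal", "central_reflex", "low_contrast"])
        specs.append(replace(
            SyntheticSpec.default(image_size, seed=int(rng.integers(2 ** 31))),
            profile_regime=str(regime), degradation=str(deg)))
    return specs


def spec_to_dict(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["image_size"] = list(d["image_size"])
    d["disc_centre"] = list(d["disc_centre"])
    d["fovea_centre"] = list(d["fovea_centre"])
    return d
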