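"""Synthetic test objects.

Three generators, mirroring the standard bench for a bladder-imaging
system:

* :func:`wire_phantom` -- thin wires at chosen depths for PSF/resolution
  characterization (wires are modelled as points in the imaging plane);
* :func:`lesion_phantom` -- diffuse random scatterers with a circular
  lesion of modified reflectivity for contrast (CR/CNR) measurements,
  like a general-purpose tissue-mimicking phantom;
* :func:`synth_bladder_bmode` -- fan-masked B-mode-like rasters of an
  anechoic bladder ellipse embedded in speckle, with binary ground-truth
  masks, emulating the difficult scenarios encountered in abdominal
  scans: a bladder only partially inside the fan, an almost empty bladder
  near the fan centre, and confounding dark regions (bone shadow/colon).

Bladder images are synthesized directly in image space so segmentation
experiments stay cheap; the RF route (simulate + beamform) remains
available for small rasters.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import scipy.ndimage

from .fieldsim import ScattererField

__all__ = [
    "FanGeometry",
    "BladderScene",
    "LabeledImage",
    "wire_phantom",
    "lesion_phantom",
    "synth_bladder_bmode",
    "make_bladder_dataset",
]

SCENARIOS = ("partial", "central", "confounder")


@dataclasses.dataclass(frozen=True)
class FanGeometry:
    """Sector geometry in pixel coordinates: apex, half opening angle, radius."""

    apex_x: float
    apex_y: float
    half_angle_rad: float
    radius_px: float

    def raster(self, shape: tuple) -> np.ndarray:
        """Boolean fan-validity mask for an (H, W) raster."""
        H, W = shape
        yy, xx = np.mgrid[0:H, 0:W]
        dx = xx - self.apex_x
        dy = yy - self.apex_y
        r = np.hypot(dx, dy)
        ang = np.arctan2(dx, np.maximum(dy, 1e-9))
        return (dy >= 0) & (np.abs(ang) <= self.half_angle_rad) & (r <= self.radius_px)


@dataclasses.dataclass(frozen=True)
class BladderScene:
    """Parameters of one synthetic bladder image.

    ``fill_level`` in [0, 1] drives the ellipse semi-axes unless they are
    given explicitly; the three scenario tags reproduce the qualitative
    image classes seen in abdominal bladder scans.
    """

    fill_level: float = 0.5
    center_mm: tuple = (0.0, 60.0)  # (lateral x, depth z)
    semi_axes_mm: tuple | None = None
    scenario: str = "central"
    clutter_level: float = 0.2
    contrast_factor: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fill_level <= 1.0:
            raise ValueError("fill_level must be in [0, 1]")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0.0 <= self.clutter_level <= 1.0:
            raise ValueError("clutter_level must be in [0, 1]")

    def resolved_semi_axes_mm(self) -> tuple:
        """Semi-axes (lateral, axial) in mm, monotone non-decreasing in fill."""
        if self.semi_axes_mm is not None:
            a, b = self.semi_axes_mm
            if a <= 0 or b <= 0:
                raise ValueError("semi-axes must be positive")
            return (float(a), float(b))
        return (12.0 + 28.0 * self.fill_level, 8.0 + 20.0 * self.fill_level)


@dataclasses.dataclass
class LabeledImage:
    """Grayscale raster with ground-truth bladder mask and fan mask."""

    image: np.ndarray  # uint8 (H, W)
    mask: np.ndarray  # bool (H, W), subset of fan
    fan: np.ndarray  # bool (H, W)
    fan_geometry: FanGeometry | None = None
    scene: BladderScene | None = None

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape or self.image.shape != self.fan.shape:
            raise ValueError("image, mask and fan shapes must match")
        if np.any(self.mask & ~self.fan):
            raise ValueError("ground-truth mask must lie inside the fan")


def wire_phantom(depths_mm, lateral_offset_mm: float = 0.0) -> ScattererField:
    """Unit-reflectivity point target at each requested depth."""
    depths = np.asarray(depths_mm, dtype=float).reshape(-1)
    if depths.size == 0 or np.any(depths <= 0):
        raise ValueError("depths must be positive")
    if len(set(depths.tolist())) != depths.size:
        raise ValueError("depths must be distinct")
    pos = np.column_stack([np.full(depths.size, lateral_offset_mm), depths])
    return ScattererField(pos, np.ones(depths.size))


def lesion_phantom(
    region_mm: tuple,
    density_per_mm2: float,
    lesion_center_mm: tuple,
    lesion_radius_mm: float,
    amplitude_ratio: float = 0.0,
    seed: int | None = None,
) -> ScattererField:
    """Diffuse speckle scatterers with a circular lesion of modified echogenicity.

    ``region_mm = (x_min, x_max, z_min, z_max)``. Scatterer count is
    Poisson with mean ``density * area``; positions are uniform;
    background reflectivities are Rayleigh-distributed and scaled by
    ``amplitude_ratio`` inside the lesion disk (0 = anechoic).
    """
    if density_per_mm2 <= 0:
        raise ValueError("density must be positive")
    if amplitude_ratio < 0:
        raise ValueError("amplitude ratio must be >= 0")
    x0, x1, z0, z1 = region_mm
    if x1 <= x0 or z1 <= z0 or z0 <= 0:
        raise ValueError("invalid region")
    rng = np.random.default_rng(seed)
    area = (x1 - x0) * (z1 - z0)
    n = rng.poisson(density_per_mm2 * area)
    xs = rng.uniform(x0, x1, n)
    zs = rng.uniform(z0, z1, n)
    refl = rng.rayleigh(1.0, n)
    inside = (xs - lesion_center_mm[0]) ** 2 + (zs - lesion_center_mm[1]) ** 2 <= lesion_radius_mm**2
    refl[inside] *= amplitude_ratio
    return ScattererField(np.column_stack([xs, zs]), refl)


def _correlated_speckle(shape: tuple, rng: np.random.Generator, corr_px: float = 3.0) -> np.ndarray:
    """Rayleigh-amplitude speckle with ~corr_px grain, unit mean."""
    sigma = corr_px / 2.355  # FWHM of the blur kernel ~ grain size
    re = scipy.ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    im = scipy.ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    env = np.hypot(re, im)
    return env / env.mean()


def synth_bladder_bmode(
    scene: BladderScene,
    shape: tuple = (720, 1056),
    px_per_mm: float | None = None,
    dynamic_range_db: float = 50.0,
) -> LabeledImage:
    """Render one fan-masked synthetic bladder B-mode image with ground truth.

    The background is log-compressed spatially correlated Rayleigh
    speckle; the bladder is an ellipse whose mean envelope is reduced by
    the scene's contrast factor, clipped to the fan. Scenario "partial"
    shifts the ellipse onto a fan border, "confounder" darkens an extra
    wedge that is not part of the ground truth, and ``clutter_level``
    raises a haze band over the near-field part of the bladder.
    The ground-truth mask is (ellipse intersect fan). Fully seeded.
    """
    H, W = shape
    if px_per_mm is None:
        px_per_mm = W / 176.0  # default field of view: 176 mm across the raster
    rng = np.random.default_rng(scene.seed)
    fan_geo = FanGeometry(
        apex_x=(W - 1) / 2.0,
        apex_y=0.0,
        half_angle_rad=math.radians(35.0),
        radius_px=1.02 * math.hypot(H, W / 2.0),
    )
    fan = fan_geo.raster(shape)

    a_mm, b_mm = scene.resolved_semi_axes_mm()
    cx = fan_geo.apex_x + scene.center_mm[0] * px_per_mm
    cy = fan_geo.apex_y + scene.center_mm[1] * px_per_mm
    if scene.scenario == "partial":
        # centre the ellipse on the left fan border at its depth
        cx = fan_geo.apex_x - (cy - fan_geo.apex_y) * math.tan(fan_geo.half_angle_rad)
    a_px = a_mm * px_per_mm
    b_px = b_mm * px_per_mm

    yy, xx = np.mgrid[0:H, 0:W]
    ellipse = ((xx - cx) / a_px) ** 2 + ((yy - cy) / b_px) ** 2 <= 1.0
    mask = ellipse & fan
    if not mask.any():
        raise ValueError("bladder ellipse lies entirely outside the fan")

    env = _correlated_speckle(shape, rng)
    env[ellipse] *= scene.contrast_factor

    if scene.scenario == "confounder":
        # dark wedge (shadow-like) on the right side of the fan, outside the bladder
        dxp = xx - fan_geo.apex_x
        dyp = np.maximum(yy - fan_geo.apex_y, 1e-9)
        ang = np.arctan2(dxp, dyp)
        r = np.hypot(dxp, dyp)
        wedge = (
            (ang >= 0.45 * fan_geo.half_angle_rad)
            & (ang <= 0.9 * fan_geo.half_angle_rad)
            & (r >= 0.45 * fan_geo.radius_px)
            & fan
            & ~ellipse
        )
        env[wedge] *= scene.contrast_factor

    if scene.clutter_level > 0:
        # near-field haze inside the upper part of the bladder
        top = cy - b_px
        haze_zone = ellipse & (yy <= top + 0.4 * b_px)
        haze = scene.clutter_level * _correlated_speckle(shape, rng, corr_px=6.0)
        env[haze_zone] += haze[haze_zone]

    env[~fan] = 0.0
    peak = env.max()
    floor = peak * 10 ** (-dynamic_range_db / 20.0)
    db = 20.0 * np.log10(np.maximum(env, floor) / peak)
    img = np.zeros(shape, dtype=np.uint8)
    img[fan] = np.round((db[fan] / dynamic_range_db + 1.0) * 255.0).astype(np.uint8)
    return LabeledImage(img, mask, fan, fan_geo, scene)


def make_bladder_dataset(
    n: int,
    scenario: str = "central",
    shape: tuple = (720, 1056),
    seed: int = 0,
    fill_range: tuple = (0.2, 0.9),
) -> list:
    """Generate ``n`` randomized labelled bladder scenes of one scenario.

    Fill level, lateral position and clutter are jittered per scene; every
    scene carries its own derived seed so the dataset is reproducible.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        fill = float(rng.uniform(*fill_range))
        cx = float(rng.uniform(-10.0, 10.0))
        cz = float(rng.uniform(50.0, 75.0))
        clutter = float(rng.uniform(0.05, 0.35))
        scene = BladderScene(
            fill_level=fill,
            center_mm=(cx, cz),
            scenario=scenario,
            clutter_level=clutter,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(synth_bladder_bmode(scene, shape=shape))
    return out
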