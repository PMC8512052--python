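"""Software reconstruction of plane-wave channel data.

Per-angle delay-and-sum (DAS) on a Cartesian grid, coherent compounding
across angles, coherence-factor (COH) and aperture-statistics (STD)
weighting, envelope detection, log compression, and fan masking.

Rasters are indexed ``[z][x]`` (axial axis first), 0-based. The coherent
compound is the mean of per-angle RF images before envelope detection.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import scipy.signal

from .fieldsim import ArrayGeometry, ChannelData, element_positions

__all__ = [
    "ReconGrid",
    "BeamformedImage",
    "BModeImage",
    "das_delay",
    "das_beamform",
    "weighted_beamform",
    "compound",
    "coherence_factor",
    "std_weight",
    "envelope",
    "log_compress",
    "fan_mask",
    "bmode_pipeline",
]


@dataclasses.dataclass(frozen=True)
class ReconGrid:
    """Cartesian reconstruction grid: lateral x and axial z extents in mm."""

    x_min_mm: float
    x_max_mm: float
    nx: int
    z_min_mm: float
    z_max_mm: float
    nz: int

    def __post_init__(self) -> None:
        if self.z_min_mm <= 0:
            raise ValueError("grid must lie at z > 0")
        if self.nx < 2 or self.nz < 2:
            raise ValueError("pixel counts must be >= 2")
        if self.x_max_mm <= self.x_min_mm or self.z_max_mm <= self.z_min_mm:
            raise ValueError("grid extents must be increasing")

    @property
    def x_mm(self) -> np.ndarray:
        return np.linspace(self.x_min_mm, self.x_max_mm, self.nx)

    @property
    def z_mm(self) -> np.ndarray:
        return np.linspace(self.z_min_mm, self.z_max_mm, self.nz)

    @property
    def dx_mm(self) -> float:
        return (self.x_max_mm - self.x_min_mm) / (self.nx - 1)

    @property
    def dz_mm(self) -> float:
        return (self.z_max_mm - self.z_min_mm) / (self.nz - 1)

    @property
    def shape(self) -> tuple:
        return (self.nz, self.nx)


@dataclasses.dataclass
class BeamformedImage:
    """Per-angle RF images, shape (n_angles, nz, nx)."""

    images: np.ndarray
    grid: ReconGrid
    method: str = "das"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[1:] != self.grid.shape:
            raise ValueError("images axes inconsistent with grid")


@dataclasses.dataclass
class BModeImage:
    """Log-compressed display raster in dB, clipped to [-dynamic_range, 0]."""

    values_db: np.ndarray
    fan: np.ndarray  # boolean validity raster, same shape
    grid: ReconGrid
    dynamic_range_db: float = 60.0

    def __post_init__(self) -> None:
        self.values_db = np.asarray(self.values_db, dtype=float)
        self.fan = np.asarray(self.fan, dtype=bool)
        if self.values_db.shape != self.grid.shape or self.fan.shape != self.grid.shape:
            raise ValueError("raster shape inconsistent with grid")


def das_delay(x_mm, z_mm, angle_rad: float, x_e_mm, c: float) -> np.ndarray:
    """Round-trip time (s) from the tilted plane wave to pixel and back to element.

    ``(z cos(theta) + x sin(theta)) / c + sqrt((x - x_e)^2 + z^2) / c`` with
    spatial inputs in mm; broadcasts over pixel and element arrays.
    """
    x = np.asarray(x_mm, dtype=float)
    z = np.asarray(z_mm, dtype=float)
    if np.any(z <= 0):
        raise ValueError("pixel depth must satisfy z > 0")
    tx = (z * math.cos(angle_rad) + x * math.sin(angle_rad)) * 1e-3 / c
    rx = np.hypot(x - np.asarray(x_e_mm, dtype=float), z) * 1e-3 / c
    return tx + rx


def _interp_record(record: np.ndarray, coord: np.ndarray) -> np.ndarray:
    """Linear interpolation of a 1-D record at fractional sample coordinates.

    Out-of-record coordinates contribute 0.
    """
    T = record.shape[0]
    i = np.floor(coord).astype(int)
    frac = coord - i
    ok = (i >= 0) & (i <= T - 2)
    ii = np.where(ok, i, 0)
    vals = record[ii] * (1 - frac) + record[ii + 1] * frac
    return np.where(ok, vals, 0.0)


def _aperture_weights(
    data: ChannelData, grid: ReconGrid, apodization, fnum
) -> np.ndarray:
    """Receive weights, shape (E, nz, nx); boxcar unless apodization/f-number set."""
    E = data.geometry.n_elements
    xe = element_positions(data.geometry)
    if apodization is None:
        w_el = np.ones(E)
    elif isinstance(apodization, str):
        if apodization != "hann":
            raise ValueError(f"unknown apodization {apodization!r}")
        w_el = np.hanning(E + 2)[1:-1]
    else:
        w_el = np.asarray(apodization, dtype=float)
        if w_el.shape != (E,):
            raise ValueError("apodization must have one weight per element")
    w = np.broadcast_to(w_el[:, None, None], (E, grid.nz, grid.nx)).copy()
    if fnum is not None:
        X = grid.x_mm[None, :]
        Z = grid.z_mm[:, None]
        for e in range(E):
            w[e] *= (np.abs(X - xe[e]) <= Z / (2.0 * fnum)).astype(float)
    return w


def delayed_aperture_stack(
    data: ChannelData, grid: ReconGrid, angle_index: int
) -> np.ndarray:
    """Delayed (but unsummed) receive samples for one angle, shape (E, nz, nx)."""
    th = data.sequence.angles_rad[angle_index]
    xe = element_positions(data.geometry)
    X = grid.x_mm[None, :]
    Z = grid.z_mm[:, None]
    fs = data.sampling_rate
    out = np.empty((data.geometry.n_elements, grid.nz, grid.nx))
    for e in range(data.geometry.n_elements):
        tau = das_delay(X, Z, th, xe[e], data.speed_of_sound)
        coord = (tau - data.t0) * fs
        out[e] = _interp_record(data.samples[angle_index, e], coord)
    return out


def coherence_factor(samples: np.ndarray, axis: int = 0, n: int | None = None) -> np.ndarray:
    """Coherence factor ``CF = |sum_e s_e|^2 / (N * sum_e |s_e|^2)`` in [0, 1].

    Defined as 0 where all aperture samples vanish. ``n`` overrides the
    element count (useful when part of the aperture is masked out).
    """
    s = np.asarray(samples, dtype=float)
    N = s.shape[axis] if n is None else n
    num = np.abs(s.sum(axis=axis)) ** 2
    den = N * (s**2).sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        cf = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(cf, 0.0, 1.0)


def std_weight(samples: np.ndarray, axis: int = 0, eps: float | None = None) -> np.ndarray:
    """Aperture-statistics weight ``|mu| / (|mu| + sigma + eps)`` in [0, 1].

    ``mu`` and ``sigma`` are the mean and population standard deviation of
    the delayed samples across the aperture. Coherent apertures (sigma
    small relative to |mu|) are kept; incoherent ones are suppressed. By
    default ``eps = 1e-12 * max|s|`` guards the all-zero aperture.
    """
    s = np.asarray(samples, dtype=float)
    if s.shape[axis] < 2:
        raise ValueError("need at least 2 aperture samples")
    mu = np.abs(s.mean(axis=axis))
    sigma = s.std(axis=axis)
    if eps is None:
        eps = 1e-12 * max(float(np.abs(s).max()), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(mu + sigma + eps > 0, mu / (mu + sigma + eps), 0.0)
    return np.clip(w, 0.0, 1.0)


def das_beamform(
    data: ChannelData,
    grid: ReconGrid,
    apodization=None,
    fnum: float | None = None,
) -> BeamformedImage:
    """Per-angle delay-and-sum reconstruction.

    Pixel value is the apodized sum over elements of the linearly
    interpolated sample at the round-trip delay; times outside the record
    contribute 0.
    """
    w = _aperture_weights(data, grid, apodization, fnum)
    imgs = np.empty((data.sequence.n_angles, grid.nz, grid.nx))
    for a in range(data.sequence.n_angles):
        stack = delayed_aperture_stack(data, grid, a)
        imgs[a] = (w * stack).sum(axis=0)
    return BeamformedImage(imgs, grid, "das")


def weighted_beamform(
    data: ChannelData,
    grid: ReconGrid,
    method: str = "coh",
    apodization=None,
    fnum: float | None = None,
) -> BeamformedImage:
    """DAS with per-pixel adaptive weighting applied per angle before compounding.

    ``method`` is "coh" (coherence factor) or "std" (aperture-statistics
    weight). The weight multiplies the DAS sum pixelwise, so the weighted
    image never exceeds the plain DAS image in magnitude.
    """
    if method not in ("coh", "std"):
        raise ValueError("method must be 'coh' or 'std'")
    w = _aperture_weights(data, grid, apodization, fnum)
    n_active = w.astype(bool).sum(axis=0)
    imgs = np.empty((data.sequence.n_angles, grid.nz, grid.nx))
    for a in range(data.sequence.n_angles):
        stack = w * delayed_aperture_stack(data, grid, a)
        das_sum = stack.sum(axis=0)
        if method == "coh":
            weight = coherence_factor(stack, axis=0)
            # rescale N from full to active aperture where f-number masking applies
            if fnum is not None:
                full = stack.shape[0]
                weight = np.clip(weight * full / np.maximum(n_active, 1), 0.0, 1.0)
        else:
            weight = std_weight(stack, axis=0)
        imgs[a] = weight * das_sum
    return BeamformedImage(imgs, grid, method)


def compound(bfi: BeamformedImage) -> np.ndarray:
    """Coherent compound: mean of the per-angle RF images (pre-envelope)."""
    if bfi.images.shape[0] < 1:
        raise ValueError("need at least one angle")
    return bfi.images.mean(axis=0)


def envelope(rf_image: np.ndarray, axis: int = 0) -> np.ndarray:
    """Envelope detection: magnitude of the analytic signal along the axial axis."""
    rf = np.asarray(rf_image, dtype=float)
    return np.abs(scipy.signal.hilbert(rf, axis=axis))


def log_compress(env: np.ndarray, dynamic_range_db: float = 60.0) -> np.ndarray:
    """``20 log10(env / max(env))`` clipped to ``[-dynamic_range, 0]`` dB."""
    if dynamic_range_db <= 0:
        raise ValueError("dynamic_range must be positive")
    env = np.asarray(env, dtype=float)
    peak = env.max()
    if peak <= 0:
        raise ValueError("cannot log-compress an all-zero image")
    floor = peak * 10 ** (-dynamic_range_db / 20.0)
    db = 20.0 * np.log10(np.maximum(env, floor) / peak)
    return np.clip(db, -dynamic_range_db, 0.0)


def fan_mask(
    grid: ReconGrid, geometry: ArrayGeometry, max_steering_rad: float
) -> np.ndarray:
    """Boolean raster of pixels inside the imaging sector.

    A pixel is valid iff it lies within the wedge bounded by rays from the
    two aperture edges tilted outward by the maximum steering angle:
    ``|x| <= aperture/2 + z * tan(theta_max)``.
    """
    half = geometry.aperture_mm / 2.0
    t = math.tan(max_steering_rad)
    X = grid.x_mm[None, :]
    Z = grid.z_mm[:, None]
    return np.abs(X) <= half + Z * t


def bmode_pipeline(
    data: ChannelData,
    grid: ReconGrid,
    method: str = "das",
    dynamic_range_db: float = 60.0,
    angle_indices=None,
    apodization=None,
    fnum: float | None = None,
) -> BModeImage:
    """Full reconstruction chain: beamform, compound, envelope, log-compress, mask.

    ``angle_indices`` selects a subset of transmitted angles for
    compounding (default: all).
    """
    if method == "das":
        bfi = das_beamform(data, grid, apodization, fnum)
    else:
        bfi = weighted_beamform(data, grid, method, apodization, fnum)
    imgs = bfi.images if angle_indices is None else bfi.images[list(angle_indices)]
    rf = BeamformedImage(imgs, grid, method)
    env = envelope(compound(rf))
    db = log_compress(env, dynamic_range_db)
    max_steer = max(abs(a) for a in data.sequence.angles_rad)
    mask = fan_mask(grid, data.geometry, max_steer)
    return BModeImage(db, mask, grid, dynamic_range_db)
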