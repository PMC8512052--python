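"""Image-quality quantification for B-mode reconstructions.

All metric inputs are *linear* envelope values taken before log
compression; the contrast ratio applies the logarithm itself. Standard
deviations are population (ddof=0) values.

Metrics
-------
* lateral point-spread-function FWHM (resolution),
* depth-dependent SNR over repeated acquisitions,
  ``SNR(z) = 20 log10(mu_z / sigma_z)``,
* contrast ratio ``CR = 20 log10(mu_lesion / mu_background)``,
* contrast-to-noise ratio
  ``CNR = (mu_bck - mu_lesion) / sqrt(sigma_bck^2 +/- sigma_lesion^2)``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .beamform import ReconGrid

__all__ = [
    "ROIStats",
    "SNRProfile",
    "PSFMeasurement",
    "PeakTruncatedError",
    "fwhm",
    "psf_lateral_fwhm",
    "snr_depth",
    "contrast_ratio",
    "cnr",
    "roi_stats",
]


class PeakTruncatedError(ValueError):
    """Raised when a profile peak has no half-maximum crossing on one side."""


@dataclasses.dataclass(frozen=True)
class ROIStats:
    """Mean/std of linear envelope values inside a region of interest."""

    mu: float
    sigma: float
    n: int
    role: str = "background"

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.n < 1:
            raise ValueError("invalid ROI statistics")


@dataclasses.dataclass(frozen=True)
class SNRProfile:
    depths_mm: np.ndarray
    snr_db: np.ndarray  # +inf where the per-depth std is exactly 0

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_mm, dtype=float)
        s = np.asarray(self.snr_db, dtype=float)
        if d.shape != s.shape:
            raise ValueError("depths and SNR values must align")
        object.__setattr__(self, "depths_mm", d)
        object.__setattr__(self, "snr_db", s)


@dataclasses.dataclass(frozen=True)
class PSFMeasurement:
    depth_mm: float
    fwhm_um: float
    method: str = "das"
    n_angles: int | None = None

    def __post_init__(self) -> None:
        if self.fwhm_um <= 0:
            raise ValueError("FWHM must be positive")


def fwhm(values: np.ndarray, coords: np.ndarray) -> float:
    """Full width at half maximum of a sampled unimodal profile.

    The two half-maximum crossings nearest the peak are each located by
    linear interpolation between the bracketing samples. A plateau at the
    maximum is resolved to its midpoint. Raises :class:`PeakTruncatedError`
    if the profile never falls below half maximum on one side.
    """
    v = np.asarray(values, dtype=float)
    x = np.asarray(coords, dtype=float)
    if v.ndim != 1 or v.shape != x.shape or v.size < 3:
        raise ValueError("need matching 1-D profile and coordinates")
    peak = v.max()
    if peak <= 0:
        raise ValueError("profile must have a positive maximum")
    at_max = np.flatnonzero(v == peak)
    ip = int(at_max[(len(at_max) - 1) // 2]) if len(at_max) > 1 else int(at_max[0])
    half = peak / 2.0

    def _cross(direction: int) -> float:
        i = ip
        while 0 <= i + direction < v.size:
            j = i + direction
            if v[j] < half:
                # interpolate between samples i (>= half) and j (< half)
                frac = (v[i] - half) / (v[i] - v[j])
                return x[i] + frac * (x[j] - x[i])
            i = j
        side = "right" if direction > 0 else "left"
        raise PeakTruncatedError(f"no half-maximum crossing on the {side} side")

    lo = _cross(-1)
    hi = _cross(+1)
    return abs(hi - lo)


def psf_lateral_fwhm(
    env: np.ndarray,
    grid: ReconGrid,
    approx_xz_mm: tuple,
    search_mm: float = 2.0,
    method: str = "das",
    n_angles: int | None = None,
) -> PSFMeasurement:
    """Lateral FWHM (um) of the point spread function near a target position.

    Finds the envelope maximum within ``search_mm`` of the approximate
    target position, extracts the lateral profile through that row and
    measures its FWHM.
    """
    env = np.asarray(env, dtype=float)
    if env.shape != grid.shape:
        raise ValueError("envelope shape inconsistent with grid")
    x0, z0 = approx_xz_mm
    xm = np.abs(grid.x_mm - x0) <= search_mm
    zm = np.abs(grid.z_mm - z0) <= search_mm
    if not xm.any() or not zm.any():
        raise ValueError("approximate target position outside the grid")
    sub = env[np.ix_(zm, xm)]
    iz, ix = np.unravel_index(np.argmax(sub), sub.shape)
    iz = int(np.flatnonzero(zm)[iz])
    ix = int(np.flatnonzero(xm)[ix])
    if iz in (0, grid.nz - 1) or ix in (0, grid.nx - 1):
        raise ValueError("PSF peak lies on the grid boundary")
    width_mm = fwhm(env[iz, :], grid.x_mm)
    return PSFMeasurement(float(grid.z_mm[iz]), width_mm * 1e3, method, n_angles)


def snr_depth(
    stack: np.ndarray,
    column: int | None = None,
    depths_mm: np.ndarray | None = None,
) -> SNRProfile:
    """Depth-dependent SNR from repeated envelope acquisitions.

    ``stack`` holds N >= 2 repetitions, shape (N, nz) or (N, nz, nx); for
    3-D input a single lateral column is analyzed (default: centre).
    Per depth, ``SNR(z) = 20 log10(mu_z / sigma_z)`` over the repetitions;
    depths with sigma exactly 0 are flagged as +inf.
    """
    a = np.asarray(stack, dtype=float)
    if a.ndim == 3:
        col = a.shape[2] // 2 if column is None else int(column)
        a = a[:, :, col]
    if a.ndim != 2:
        raise ValueError("stack must be (N, nz) or (N, nz, nx)")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 repetitions")
    mu = a.mean(axis=0)
    sigma = a.std(axis=0)
    # identical repetitions have zero spread by definition; guard the float mean
    degenerate = (np.ptp(a, axis=0) == 0) | (sigma == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(
            degenerate, np.inf, 20.0 * np.log10(mu / np.where(degenerate, 1.0, sigma))
        )
    if depths_mm is None:
        depths_mm = np.arange(a.shape[1], dtype=float)
    return SNRProfile(depths_mm, snr)


def contrast_ratio(lesion: ROIStats, background: ROIStats) -> float:
    """Contrast ratio ``CR = 20 log10(mu_lesion / mu_bck)`` in dB.

    Strongly negative for an anechoic lesion; -inf if the lesion mean is
    not positive.
    """
    if background.mu <= 0:
        raise ValueError("background mean must be positive")
    if lesion.mu <= 0:
        return -math.inf
    return 20.0 * math.log10(lesion.mu / background.mu)


def cnr(lesion: ROIStats, background: ROIStats, variance_mode: str = "sum") -> float:
    """Contrast-to-noise ratio ``(mu_bck - mu_lesion) / sqrt(var term)``.

    ``variance_mode`` selects the denominator: "sum" (default) uses
    ``sigma_bck^2 + sigma_lesion^2``; "difference" uses
    ``sigma_bck^2 - sigma_lesion^2`` and requires ``sigma_bck > sigma_lesion``.
    """
    if variance_mode == "sum":
        var = background.sigma**2 + lesion.sigma**2
    elif variance_mode == "difference":
        var = background.sigma**2 - lesion.sigma**2
    else:
        raise ValueError("variance_mode must be 'sum' or 'difference'")
    if var <= 0:
        raise ValueError("nonpositive variance term for the chosen mode")
    return (background.mu - lesion.mu) / math.sqrt(var)


def roi_stats(
    env: np.ndarray,
    grid: ReconGrid,
    center_mm: tuple,
    radius_mm: float,
    fan: np.ndarray | None = None,
    role: str = "background",
) -> ROIStats:
    """Statistics of envelope pixels whose centres lie inside a circular ROI.

    Restricted to the fan-valid region when a fan mask is supplied.
    """
    env = np.asarray(env, dtype=float)
    if env.shape != grid.shape:
        raise ValueError("envelope shape inconsistent with grid")
    cx, cz = center_mm
    X = grid.x_mm[None, :]
    Z = grid.z_mm[:, None]
    inside = (X - cx) ** 2 + (Z - cz) ** 2 <= radius_mm**2
    if fan is not None:
        inside &= np.asarray(fan, dtype=bool)
    vals = env[inside]
    if vals.size == 0:
        raise ValueError("ROI contains no valid pixels")
    return ROIStats(float(vals.mean()), float(vals.std()), int(vals.size), role)
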