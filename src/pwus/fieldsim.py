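"""Point-source acoustic field synthesis and RF channel-data simulation.

Models a linear phased array transmitting tilted plane waves and receiving
echoes from point scatterers, producing pre-beamformed per-element RF
records ("channel data") like those streamed by a research ultrasound
front end.

Conventions
-----------
* Lateral coordinate ``x`` in mm, positive to the right; axial coordinate
  ``z`` in mm, depth, positive away from the array. Elements lie on the
  line ``z = 0``.
* Angles are stored in radians. A steering angle ``theta`` tilts the
  transmitted wavefront so that it propagates along
  ``(sin(theta), cos(theta))``.
* Time origin ``t = 0`` is the instant the tilted plane wavefront passes
  the array centre ``(x, z) = (0, 0)``; the transmit path length to a
  point ``(x, z)`` is therefore ``z*cos(theta) + x*sin(theta)``.
* The echo waveform is a windowed tone burst *centred* on the geometric
  arrival time, so the envelope peak of an echo coincides with its
  round-trip delay.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

SPEED_OF_SOUND = 1540.0
"""Default speed of sound in soft tissue / phantom material (m/s)."""


@dataclasses.dataclass(frozen=True)
class ArrayGeometry:
    """Element layout and carrier frequency of the phased array.

    Defaults describe a 32-element, 500 um pitch, 3 MHz probe. The
    elevation size is carried as metadata only; the simulation is
    two-dimensional (imaging plane).
    """

    n_elements: int = 32
    pitch_mm: float = 0.5
    kerf_mm: float = 0.05
    center_frequency: float = 3e6
    elevation_size_mm: float = 11.5

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if not self.pitch_mm > self.kerf_mm >= 0:
            raise ValueError("require pitch > kerf >= 0")
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")

    @property
    def aperture_mm(self) -> float:
        """Lateral span of the element centres, ``(n-1) * pitch``."""
        return (self.n_elements - 1) * self.pitch_mm


@dataclasses.dataclass(frozen=True)
class PlaneWaveSequence:
    """Transmit sequence: steering angles and burst parameters."""

    angles_rad: tuple
    tx_frequency: float = 3e6
    burst_cycles: int = 3
    voltage: float = 1.0

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles_rad)
        object.__setattr__(self, "angles_rad", angles)
        if len(angles) == 0:
            raise ValueError("angles must be non-empty")
        if any(abs(a) >= math.pi / 2 for a in angles):
            raise ValueError("|angle| must be < 90 degrees")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("angles must be strictly increasing")
        if self.tx_frequency <= 0 or self.burst_cycles < 1:
            raise ValueError("invalid burst parameters")

    @classmethod
    def from_span(
        cls,
        n_angles: int,
        span_deg: float = 16.0,
        tx_frequency: float = 3e6,
        burst_cycles: int = 3,
        voltage: float = 1.0,
    ) -> "PlaneWaveSequence":
        """Evenly spaced angles over ``+-span_deg`` (a single angle is 0)."""
        if n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if n_angles == 1:
            deg = np.array([0.0])
        else:
            deg = np.linspace(-span_deg, span_deg, n_angles)
        return cls(tuple(np.deg2rad(deg)), tx_frequency, burst_cycles, voltage)

    @property
    def n_angles(self) -> int:
        return len(self.angles_rad)


@dataclasses.dataclass(frozen=True)
class ScattererField:
    """Point reflectors: positions (x, z) in mm with z > 0, and amplitudes."""

    positions_mm: np.ndarray  # (S, 2) columns (x, z)
    reflectivities: np.ndarray  # (S,)

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions_mm, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, 2)
        refl = np.asarray(self.reflectivities, dtype=float).reshape(-1)
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "reflectivities", refl)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (S, 2) array of (x, z) mm")
        if pos.shape[0] != refl.shape[0]:
            raise ValueError("positions and reflectivities lengths differ")
        if np.any(refl < 0):
            raise ValueError("reflectivities must be nonnegative")
        if pos.shape[0] and np.any(pos[:, 1] <= 0):
            raise ValueError("all scatterer depths must satisfy z > 0")

    def __len__(self) -> int:
        return self.positions_mm.shape[0]

    def __add__(self, other: "ScattererField") -> "ScattererField":
        return ScattererField(
            np.vstack([self.positions_mm, other.positions_mm]),
            np.concatenate([self.reflectivities, other.reflectivities]),
        )

    @classmethod
    def from_table(cls, path) -> "ScattererField":
        """Read a plain-text table: columns x_mm, z_mm[, reflectivity]."""
        arr = np.atleast_2d(np.loadtxt(path, dtype=float))
        if arr.shape[1] == 2:
            refl = np.ones(arr.shape[0])
        elif arr.shape[1] == 3:
            refl = arr[:, 2]
        else:
            raise ValueError("expected 2 or 3 columns (x_mm, z_mm[, reflectivity])")
        return cls(arr[:, :2], refl)

    def to_table(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.positions_mm, self.reflectivities]),
            header="x_mm z_mm reflectivity",
        )


@dataclasses.dataclass
class ChannelData:
    """Per-angle, per-element RF records with sampling metadata.

    ``samples`` has shape (n_angles, n_elements, n_samples) and holds
    real-valued RF amplitudes.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float
    speed_of_sound: float
    geometry: ArrayGeometry
    sequence: PlaneWaveSequence

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3:
            raise ValueError("samples must be 3-D [angle][element][sample]")
        a, e, _ = self.samples.shape
        if a != self.sequence.n_angles or e != self.geometry.n_elements:
            raise ValueError("samples axes inconsistent with sequence/geometry")
        if self.sampling_rate > 50e6:
            raise ValueError("sampling_rate exceeds the 50 MSa/s hardware limit")
        if self.sampling_rate <= 2 * self.sequence.tx_frequency:
            raise ValueError("sampling_rate must exceed twice the transmit frequency")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[2]


def element_positions(geometry: ArrayGeometry) -> np.ndarray:
    """Lateral element-centre positions in mm, centred on 0."""
    n = geometry.n_elements
    return (np.arange(n) - (n - 1) / 2.0) * geometry.pitch_mm


def steering_delays(
    geometry: ArrayGeometry, angle_rad: float, c: float = SPEED_OF_SOUND
) -> np.ndarray:
    """Per-element transmit delays (s) for a plane wave steered to ``angle_rad``.

    Delays are linear in element position, ``x_e * sin(angle) / c``, and
    shifted so the earliest-firing element has delay 0.
    """
    if abs(angle_rad) >= math.pi / 2:
        raise ValueError("|angle| must be < 90 degrees")
    tau = element_positions(geometry) * 1e-3 * math.sin(angle_rad) / c
    return tau - tau.min()


def _sub_element_sources(geometry: ArrayGeometry, sources_per_element: int) -> np.ndarray:
    """Lateral positions (mm) of point sources subdividing each element."""
    width = geometry.pitch_mm - geometry.kerf_mm
    offs = ((np.arange(sources_per_element) + 0.5) / sources_per_element - 0.5) * width
    return (element_positions(geometry)[:, None] + offs[None, :])  # (E, S)


def pressure_field(
    geometry: ArrayGeometry,
    delays: np.ndarray,
    x_mm: np.ndarray,
    z_mm: np.ndarray,
    frequency: float | None = None,
    c: float = SPEED_OF_SOUND,
    sources_per_element: int = 4,
) -> np.ndarray:
    """Maximum-amplitude map of the monochromatic transmit field.

    Each element is subdivided into ``sources_per_element`` point sources;
    the field is the coherent sum of spherical waves (1/r amplitude decay,
    phase from travel time plus the element's firing delay), evaluated at
    the broadcast grid of ``x_mm``/``z_mm`` points in the z > 0 half plane.
    """
    x = np.asarray(x_mm, dtype=float)
    z = np.asarray(z_mm, dtype=float)
    x, z = np.broadcast_arrays(x, z)
    if np.any(z <= 0):
        raise ValueError("field grid must lie in the z > 0 half-plane")
    f = geometry.center_frequency if frequency is None else float(frequency)
    delays = np.asarray(delays, dtype=float)
    if delays.shape != (geometry.n_elements,):
        raise ValueError("one delay per element required")
    src = _sub_element_sources(geometry, sources_per_element)  # (E, S) mm
    field = np.zeros(x.shape, dtype=complex)
    for e in range(geometry.n_elements):
        for xs in src[e]:
            r_mm = np.hypot(x - xs, z)
            travel = r_mm * 1e-3 / c + delays[e]
            field += np.exp(-2j * math.pi * f * travel) / r_mm
    return np.abs(field)


def far_field_scan(
    geometry: ArrayGeometry,
    delays: np.ndarray,
    angles_deg: np.ndarray,
    radius_mm: float = 150.0,
    frequency: float | None = None,
    c: float = SPEED_OF_SOUND,
    sources_per_element: int = 4,
) -> np.ndarray:
    """Field amplitude on an arc of fixed radius, one value per scan angle."""
    ang = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return pressure_field(
        geometry,
        delays,
        radius_mm * np.sin(ang),
        radius_mm * np.cos(ang),
        frequency=frequency,
        c=c,
        sources_per_element=sources_per_element,
    )


def tone_burst(t: np.ndarray, frequency: float, n_cycles: int, shape: str = "hann") -> np.ndarray:
    """Windowed tone burst centred at t = 0 with support ``|t| <= Tb/2``.

    ``shape`` is "hann" (cosine carrier under a Hann window; default) or
    "square" (hard-switched rectangular burst as driven by a tri-state
    pulser).
    """
    t = np.asarray(t, dtype=float)
    tb = n_cycles / frequency
    inside = np.abs(t) <= tb / 2
    out = np.zeros_like(t)
    if shape == "hann":
        out[inside] = np.cos(2 * math.pi * frequency * t[inside]) * (
            0.5 * (1 + np.cos(2 * math.pi * t[inside] / tb))
        )
    elif shape == "square":
        out[inside] = np.sign(np.cos(2 * math.pi * frequency * t[inside]))
    else:
        raise ValueError(f"unknown burst shape {shape!r}")
    return out


def echo_arrival_time(
    x_mm: float, z_mm: float, angle_rad: float, x_e_mm: float, c: float = SPEED_OF_SOUND
) -> float:
    """Round-trip time (s): plane-wave transmit path plus receive path to element."""
    tx = (z_mm * math.cos(angle_rad) + x_mm * math.sin(angle_rad)) * 1e-3 / c
    rx = math.hypot(x_mm - x_e_mm, z_mm) * 1e-3 / c
    return tx + rx


def simulate_channel_data(
    scatterers: ScattererField,
    geometry: ArrayGeometry,
    sequence: PlaneWaveSequence,
    sampling_rate: float = 40e6,
    c: float = SPEED_OF_SOUND,
    noise_std: float = 0.0,
    seed: int | None = None,
    n_samples: int | None = None,
    t0: float = 0.0,
    burst_shape: str = "hann",
    quantize_bits: int | None = None,
) -> ChannelData:
    """Synthesize pre-beamformed RF channel data for a scatterer field.

    For every plane-wave angle and scatterer, an echo arrives at element
    ``e`` at ``t = (z cos(theta) + x sin(theta))/c + sqrt((x-x_e)^2+z^2)/c``
    as a ``burst_cycles``-cycle windowed tone at the transmit frequency,
    with amplitude proportional to reflectivity and 1/r receive spreading.
    Echoes superpose linearly; i.i.d. Gaussian noise of ``noise_std`` is
    added afterwards. Reproducible given ``seed``.

    If ``n_samples`` is omitted the record is sized to contain the latest
    echo; otherwise scatterers falling beyond the configured record raise
    ``ValueError``.
    """
    if noise_std < 0:
        raise ValueError("noise_std must be >= 0")
    fs = float(sampling_rate)
    f = sequence.tx_frequency
    tb = sequence.burst_cycles / f
    xe = element_positions(geometry) * 1e-3  # (E,) m
    E = geometry.n_elements
    angles = np.asarray(sequence.angles_rad)
    S = len(scatterers)

    if S:
        xs = scatterers.positions_mm[:, 0] * 1e-3
        zs = scatterers.positions_mm[:, 1] * 1e-3
        r_rx = np.hypot(xs[:, None] - xe[None, :], zs[:, None])  # (S, E) m
        taus = []
        for th in angles:
            tx = (zs * math.cos(th) + xs * math.sin(th)) / c
            taus.append(tx[:, None] + r_rx / c)
        tau_max = max(float(t.max()) for t in taus)
    else:
        tau_max = 0.0

    if n_samples is None:
        T = int(math.ceil((tau_max + tb / 2 - t0) * fs)) + 4
        T = max(T, 16)
    else:
        T = int(n_samples)
        if S and tau_max + tb / 2 > t0 + (T - 1) / fs:
            raise ValueError("scatterer echo falls beyond the configured record length")

    out = np.zeros((len(angles), E, T))
    if S:
        amp = (scatterers.reflectivities[:, None] / (r_rx * 1e3)) * sequence.voltage
        L = int(math.ceil(tb * fs)) + 3
        offs = np.arange(L)
        e_idx = np.broadcast_to(np.arange(E)[None, :, None], (S, E, L))
        for a in range(len(angles)):
            tau = taus[a]
            i0 = np.floor((tau - tb / 2 - t0) * fs).astype(int) - 1
            idx = i0[:, :, None] + offs[None, None, :]
            t = t0 + idx / fs
            w = tone_burst(t - tau[:, :, None], f, sequence.burst_cycles, burst_shape)
            w = w * amp[:, :, None]
            ok = (idx >= 0) & (idx < T)
            np.add.at(out[a], (e_idx[ok], idx[ok]), w[ok])

    if noise_std > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_std, out.shape)

    if quantize_bits is not None:
        peak = np.abs(out).max()
        if peak > 0:
            step = peak / (2 ** (quantize_bits - 1) - 1)
            out = np.round(out / step) * step

    return ChannelData(out, fs, t0, c, geometry, sequence)
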