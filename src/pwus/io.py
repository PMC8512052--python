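"""Persistence: a self-describing HDF5 frame container.

One file holds one payload -- channel data, per-angle beamformed images,
a B-mode raster or a labelled image -- together with the acquisition and
reconstruction metadata needed to re-run the processing (array geometry,
transmit sequence, sampling parameters, grid, software version, seed).

Layout (schema version 1)
-------------------------
Root attributes: ``format = "pwus-frame"``, ``schema_version``, ``kind``.
Group ``payload/`` holds the numeric datasets of the payload kind; group
``meta/`` stores structured metadata (geometry, sequence, grid) plus a
free-form JSON attribute ``extra``. Files begin with the HDF5 signature
bytes ``\\x89HDF\\r\\n\\x1a\\n``.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from . import __version__
from .beamform import BeamformedImage, BModeImage, ReconGrid
from .fieldsim import ArrayGeometry, ChannelData, PlaneWaveSequence
from .phantoms import BladderScene, FanGeometry, LabeledImage

__all__ = [
    "FrameContainer",
    "write_frame",
    "read_frame",
    "FrameFormatError",
    "UnsupportedVersionError",
]

SCHEMA_VERSION = 1
MAGIC = b"\x89HDF\r\n\x1a\n"
KINDS = ("channel_data", "beamformed", "bmode", "labeled_image")


class FrameFormatError(IOError):
    """The file is not a readable frame container (foreign or corrupt)."""


class UnsupportedVersionError(IOError):
    """The file is a frame container of a newer, unsupported schema."""


@dataclasses.dataclass
class FrameContainer:
    kind: str
    payload: object
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown payload kind {self.kind!r}; expected one of {KINDS}")


def _write_geometry(grp: h5py.Group, g: ArrayGeometry) -> None:
    for k, v in dataclasses.asdict(g).items():
        grp.attrs[k] = v


def _read_geometry(grp: h5py.Group) -> ArrayGeometry:
    return ArrayGeometry(
        n_elements=int(grp.attrs["n_elements"]),
        pitch_mm=float(grp.attrs["pitch_mm"]),
        kerf_mm=float(grp.attrs["kerf_mm"]),
        center_frequency=float(grp.attrs["center_frequency"]),
        elevation_size_mm=float(grp.attrs["elevation_size_mm"]),
    )


def _write_sequence(grp: h5py.Group, s: PlaneWaveSequence) -> None:
    grp.create_dataset("angles_rad", data=np.asarray(s.angles_rad))
    grp.attrs["tx_frequency"] = s.tx_frequency
    grp.attrs["burst_cycles"] = s.burst_cycles
    grp.attrs["voltage"] = s.voltage


def _read_sequence(grp: h5py.Group) -> PlaneWaveSequence:
    return PlaneWaveSequence(
        tuple(grp["angles_rad"][()]),
        tx_frequency=float(grp.attrs["tx_frequency"]),
        burst_cycles=int(grp.attrs["burst_cycles"]),
        voltage=float(grp.attrs["voltage"]),
    )


def _write_grid(grp: h5py.Group, g: ReconGrid) -> None:
    for k, v in dataclasses.asdict(g).items():
        grp.attrs[k] = v


def _read_grid(grp: h5py.Group) -> ReconGrid:
    a = grp.attrs
    return ReconGrid(
        float(a["x_min_mm"]), float(a["x_max_mm"]), int(a["nx"]),
        float(a["z_min_mm"]), float(a["z_max_mm"]), int(a["nz"]),
    )


def write_frame(container: FrameContainer, path) -> None:
    """Write a container to a single self-describing HDF5 file."""
    kind, payload = container.kind, container.payload
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "pwus-frame"
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = kind
        f.attrs["software_version"] = __version__
        pay = f.create_group("payload")
        meta = f.create_group("meta")
        if kind == "channel_data":
            cd: ChannelData = payload
            pay.create_dataset("samples", data=cd.samples)
            pay.attrs["sampling_rate"] = cd.sampling_rate
            pay.attrs["t0"] = cd.t0
            pay.attrs["speed_of_sound"] = cd.speed_of_sound
            _write_geometry(meta.create_group("geometry"), cd.geometry)
            _write_sequence(meta.create_group("sequence"), cd.sequence)
        elif kind == "beamformed":
            bf: BeamformedImage = payload
            pay.create_dataset("images", data=bf.images)
            pay.attrs["method"] = bf.method
            _write_grid(meta.create_group("grid"), bf.grid)
        elif kind == "bmode":
            bm: BModeImage = payload
            pay.create_dataset("values_db", data=bm.values_db)
            pay.create_dataset("fan", data=bm.fan)
            pay.attrs["dynamic_range_db"] = bm.dynamic_range_db
            _write_grid(meta.create_group("grid"), bm.grid)
        elif kind == "labeled_image":
            li: LabeledImage = payload
            pay.create_dataset("image", data=li.image)
            pay.create_dataset("mask", data=li.mask)
            pay.create_dataset("fan", data=li.fan)
            if li.fan_geometry is not None:
                fg = meta.create_group("fan_geometry")
                for k, v in dataclasses.asdict(li.fan_geometry).items():
                    fg.attrs[k] = v
            if li.scene is not None:
                meta.attrs["scene"] = json.dumps(dataclasses.asdict(li.scene))
        meta.attrs["extra"] = json.dumps(container.meta)


def read_frame(path) -> FrameContainer:
    """Exact inverse of :func:`write_frame`.

    Raises :class:`FrameFormatError` for foreign or corrupt files and
    :class:`UnsupportedVersionError` for containers written by a newer
    schema.
    """
    if not h5py.is_hdf5(path):
        raise FrameFormatError(f"{path} is not a frame container")
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "pwus-frame":
                raise FrameFormatError(f"{path} is not a frame container")
            version = int(f.attrs["schema_version"])
            if version > SCHEMA_VERSION:
                raise UnsupportedVersionError(
                    f"schema version {version} newer than supported {SCHEMA_VERSION}"
                )
            kind = str(f.attrs["kind"])
            pay = f["payload"]
            meta = f["meta"]
            extra = json.loads(meta.attrs["extra"])
            if kind == "channel_data":
                payload = ChannelData(
                    pay["samples"][()],
                    float(pay.attrs["sampling_rate"]),
                    float(pay.attrs["t0"]),
                    float(pay.attrs["speed_of_sound"]),
                    _read_geometry(meta["geometry"]),
                    _read_sequence(meta["sequence"]),
                )
            elif kind == "beamformed":
                payload = BeamformedImage(
                    pay["images"][()], _read_grid(meta["grid"]), str(pay.attrs["method"])
                )
            elif kind == "bmode":
                payload = BModeImage(
                    pay["values_db"][()],
                    pay["fan"][()].astype(bool),
                    _read_grid(meta["grid"]),
                    float(pay.attrs["dynamic_range_db"]),
                )
            elif kind == "labeled_image":
                fan_geo = None
                if "fan_geometry" in meta:
                    a = meta["fan_geometry"].attrs
                    fan_geo = FanGeometry(
                        float(a["apex_x"]), float(a["apex_y"]),
                        float(a["half_angle_rad"]), float(a["radius_px"]),
                    )
                scene = None
                if "scene" in meta.attrs:
                    d = json.loads(meta.attrs["scene"])
                    d["center_mm"] = tuple(d["center_mm"])
                    if d.get("semi_axes_mm") is not None:
                        d["semi_axes_mm"] = tuple(d["semi_axes_mm"])
                    scene = BladderScene(**d)
                payload = LabeledImage(
                    pay["image"][()].astype(np.uint8),
                    pay["mask"][()].astype(bool),
                    pay["fan"][()].astype(bool),
                    fan_geo,
                    scene,
                )
            else:
                raise FrameFormatError(f"unknown payload kind {kind!r}")
    except (UnsupportedVersionError, FrameFormatError):
        raise
    except (OSError, KeyError) as exc:
        raise FrameFormatError(f"corrupt frame container {path}: {exc}") from exc
    return FrameContainer(kind, payload, extra)
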