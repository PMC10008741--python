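"""Shared geometry, grids, acquisition arithmetic and volume I/O.

Conventions used throughout the package:

* axis order is ``(z axial, x lateral, y elevation)`` for every volume and
  every coordinate triple;
* physical lengths are millimetres internally, frequencies Hz, times s;
* voxel index ``(0, 0, 0)`` maps to the grid origin (voxel-*center*
  convention) and indices are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

__all__ = [
    "SOUND_SPEED_M_S",
    "ProbeGeometry",
    "ImagingGrid",
    "VolumeSequence",
    "AcquisitionPlan",
    "FormatError",
    "wavelength_um",
    "truncate",
    "plan_acquisition",
    "read_volume_sequence",
    "write_volume_sequence",
]

#: Default speed of sound in soft tissue.  1540 m/s is the conventional
#: value and the one consistent with a 98.6 µm half wavelength at 7.81 MHz.
SOUND_SPEED_M_S = 1540.0


class FormatError(ValueError):
    """A volume file is malformed; the message names the offending field."""


def wavelength_um(center_frequency_hz: float, sound_speed_m_s: float = SOUND_SPEED_M_S) -> float:
    """Acoustic wavelength in micrometres.

    Parameters
    ----------
    center_frequency_hz : float
        Transmit center frequency in Hz; must be positive.
    sound_speed_m_s : float
        Medium sound speed in m/s; must be positive.

    Returns
    -------
    float
        ``sound_speed / frequency`` expressed in µm.
    """
    if center_frequency_hz <= 0:
        raise ValueError(f"center_frequency_hz must be positive, got {center_frequency_hz}")
    if sound_speed_m_s <= 0:
        raise ValueError(f"sound_speed_m_s must be positive, got {sound_speed_m_s}")
    return sound_speed_m_s / center_frequency_hz * 1e6


def truncate(value: float, decimals: int = 1) -> float:
    """Truncate (not round) toward zero at ``decimals`` decimal places.

    Display helper: e.g. a λ/20 voxel of 9.859 µm is conventionally printed
    as 9.8 µm.
    """
    factor = 10.0 ** decimals
    return math.trunc(value * factor) / factor


@dataclass(frozen=True)
class ProbeGeometry:
    """Planar matrix-array transducer geometry.

    The default constructor arguments describe a 32×32, 0.3 mm pitch,
    7.81 MHz / 60% bandwidth matrix probe.  Element positions lie on a
    regular lattice in the z=0 plane, centered on the origin.
    """

    n_elements_x: int = 32
    n_elements_y: int = 32
    pitch_mm: float = 0.3
    center_frequency_hz: float = 7.81e6
    fractional_bandwidth: float = 0.6

    def __post_init__(self) -> None:
        if self.n_elements_x < 1 or self.n_elements_y < 1:
            raise ValueError("element counts must be >= 1")
        if self.pitch_mm <= 0:
            raise ValueError(f"pitch_mm must be positive, got {self.pitch_mm}")
        if self.center_frequency_hz <= 0:
            raise ValueError("center_frequency_hz must be positive")

    @property
    def n_elements(self) -> int:
        return self.n_elements_x * self.n_elements_y

    @property
    def wavelength_mm(self) -> float:
        return wavelength_um(self.center_frequency_hz) * 1e-3

    def element_positions(self) -> np.ndarray:
        """(n_elements, 3) array of (z, x, y) positions in mm, z = 0.

        Raster order: x fastest, then y; lattice centered at the origin.
        """
        ix = np.arange(self.n_elements_x) - (self.n_elements_x - 1) / 2.0
        iy = np.arange(self.n_elements_y) - (self.n_elements_y - 1) / 2.0
        xx, yy = np.meshgrid(ix * self.pitch_mm, iy * self.pitch_mm, indexing="xy")
        pos = np.zeros((self.n_elements, 3))
        pos[:, 1] = xx.ravel()
        pos[:, 2] = yy.ravel()
        return pos


@dataclass(frozen=True)
class ImagingGrid:
    """Regular 3-D voxel grid in (z, x, y) order, voxel-center convention."""

    origin_mm: tuple[float, float, float]
    spacing_mm: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be strictly positive, got {self.spacing_mm}")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be >= 1 per axis, got {self.shape}")
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))
        object.__setattr__(self, "spacing_mm", tuple(float(v) for v in self.spacing_mm))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent per axis: shape × spacing."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinate vectors (z, x, y) in mm."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a]) for a in range(3)
        )

    def index_to_mm(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to mm coordinates."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin_mm) + index * np.asarray(self.spacing_mm)

    def mm_to_index(self, position_mm: np.ndarray) -> np.ndarray:
        """Map mm coordinates (..., 3) to fractional voxel indices."""
        position_mm = np.asarray(position_mm, dtype=float)
        return (position_mm - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def contains(self, position_mm: np.ndarray) -> np.ndarray:
        """Boolean mask: does each point fall inside the voxel lattice?"""
        idx = self.mm_to_index(position_mm)
        shape = np.asarray(self.shape)
        return np.all((idx > -0.5) & (idx < shape - 0.5), axis=-1)

    def center_mm(self) -> np.ndarray:
        return np.asarray(self.origin_mm) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.spacing_mm
        )


@dataclass
class VolumeSequence:
    """Time-ordered stack of volumes sharing one grid.

    ``frames`` has shape (n_frames, nz, nx, ny) and may be real (envelope)
    or complex (pre-envelope beamformed data).
    """

    frames: np.ndarray
    grid: ImagingGrid
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError(f"frames must be 4-D (t, z, x, y), got ndim={self.frames.ndim}")
        if tuple(self.frames.shape[1:]) != tuple(self.grid.shape):
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} does not match grid shape {self.grid.shape}"
            )
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class AcquisitionPlan:
    """Continuous-streaming acquisition bookkeeping.

    Defaults reproduce a 5-angle, 1024-sample, 100-volume-block acquisition
    on four synchronized 256-channel systems at 500 volumes/s for 100 000
    volumes.
    """

    n_angles: int = 5
    samples_per_channel: int = 1024
    volumes_per_block: int = 100
    n_systems: int = 4
    channels_per_system: int = 256
    bytes_per_sample: int = 2
    volume_rate: float = 500.0
    total_volumes: int = 100_000

    def __post_init__(self) -> None:
        for name in (
            "n_angles",
            "samples_per_channel",
            "volumes_per_block",
            "n_systems",
            "channels_per_system",
            "bytes_per_sample",
            "total_volumes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.volume_rate <= 0:
            raise ValueError("volume_rate must be positive")
        if self.total_volumes % self.volumes_per_block != 0:
            raise ValueError("total_volumes must be divisible by volumes_per_block")


def plan_acquisition(
    plan: AcquisitionPlan, block_bytes_per_system: int | None = None
) -> dict[str, float]:
    """Exact timing and storage arithmetic for a streaming acquisition.

    ``block_bytes_per_system`` overrides the derived per-system block size
    (samples × angles × volumes × channels × bytes/sample); vendor buffer
    padding means the measured figure can differ from the naive product, so
    a measured value may be supplied directly.
    """
    if block_bytes_per_system is None:
        block_bytes_per_system = (
            plan.samples_per_channel
            * plan.n_angles
            * plan.volumes_per_block
            * plan.channels_per_system
            * plan.bytes_per_sample
        )
    n_blocks = plan.total_volumes // plan.volumes_per_block
    block_bytes_total = plan.n_systems * block_bytes_per_system
    return {
        "block_bytes_per_system": float(block_bytes_per_system),
        "block_bytes_total": float(block_bytes_total),
        "dataset_bytes_total": float(block_bytes_total * n_blocks),
        "block_duration_s": plan.volumes_per_block / plan.volume_rate,
        "total_duration_s": plan.total_volumes / plan.volume_rate,
        "n_blocks": float(n_blocks),
    }


# ---------------------------------------------------------------------------
# Volume sequence I/O: HDF5 (dataset "frames" + attrs) and shaped TIFF.
# ---------------------------------------------------------------------------

_H5_ATTRS = ("spacing_mm", "origin_mm", "frame_rate")


def write_volume_sequence(seq: VolumeSequence, path: str | Path) -> None:
    """Write a sequence to ``.h5``/``.hdf5`` or ``.tif``/``.tiff`` by suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("frames", data=seq.frames)
            dset.attrs["spacing_mm"] = np.asarray(seq.grid.spacing_mm)
            dset.attrs["origin_mm"] = np.asarray(seq.grid.origin_mm)
            dset.attrs["frame_rate"] = float(seq.frame_rate)
    elif suffix in {".tif", ".tiff"}:
        metadata = {
            "spacing_mm": list(seq.grid.spacing_mm),
            "origin_mm": list(seq.grid.origin_mm),
            "frame_rate": float(seq.frame_rate),
        }
        tifffile.imwrite(path, seq.frames, metadata=metadata)
    else:
        raise FormatError(f"unsupported volume format {suffix!r} (use .h5 or .tiff)")


def _grid_from_meta(shape, spacing_mm, origin_mm) -> ImagingGrid:
    return ImagingGrid(
        origin_mm=tuple(float(v) for v in origin_mm),
        spacing_mm=tuple(float(v) for v in spacing_mm),
        shape=tuple(int(v) for v in shape),
    )


def read_volume_sequence(path: str | Path) -> VolumeSequence:
    """Read a sequence written by :func:`write_volume_sequence`."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            if "frames" not in f:
                raise FormatError(f"{path}: missing dataset 'frames'")
            dset = f["frames"]
            for attr in _H5_ATTRS:
                if attr not in dset.attrs:
                    raise FormatError(f"{path}: missing attribute {attr!r}")
            frames = dset[...]
            grid = _grid_from_meta(frames.shape[1:], dset.attrs["spacing_mm"], dset.attrs["origin_mm"])
            return VolumeSequence(frames, grid, float(dset.attrs["frame_rate"]))
    if suffix in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        for key in _H5_ATTRS:
            if key not in meta:
                raise FormatError(f"{path}: missing metadata {key!r}")
        if frames.ndim != 4:
            raise FormatError(f"{path}: expected 4-D frames, got shape {frames.shape}")
        grid = _grid_from_meta(frames.shape[1:], meta["spacing_mm"], meta["origin_mm"])
        return VolumeSequence(frames, grid, float(meta["frame_rate"]))
    raise FormatError(f"unsupported volume format {suffix!r} (use .h5 or .tiff)")
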