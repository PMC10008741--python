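"""3-D plane-wave delay-and-sum reconstruction with coherent compounding.

The delay law for a tilted plane wave uses direction cosines normalized to
a unit vector: for tilt angles (θ_lat, θ_elev) the propagation direction is
u = (sin θ_lat, sin θ_elev, √(1 − sin²θ_lat − sin²θ_elev)) in (x, y, z),
so the transmit delay to a voxel r is (r·u)/c measured from the array
plane, and the receive delay is the element–voxel path length over c.
For single-tilt angles this reduces to the familiar
(z cos θ + x sin θ)/c.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .core import ImagingGrid, ProbeGeometry, VolumeSequence

__all__ = [
    "PlaneWaveScheme",
    "RFDataSet",
    "transmit_delay",
    "das_beamform",
    "compound",
    "envelope",
    "read_rf",
    "write_rf",
]


@dataclass
class RFDataSet:
    """Multi-angle RF channel data: ``data`` is (n_angles, n_elements, n_samples)."""

    data: np.ndarray
    probe: ProbeGeometry
    angles_deg: list[tuple[float, float]]
    sample_rate_hz: float
    sound_speed_m_s: float = 1540.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_angles, n_elements, n_samples)")
        if self.data.shape[0] != len(self.angles_deg):
            raise ValueError("angle count mismatch")
        if self.data.shape[1] != self.probe.n_elements:
            raise ValueError("element count mismatch")


@dataclass(frozen=True)
class PlaneWaveScheme:
    """Compounding scheme: tilt angle list plus medium/sampling constants."""

    angles_deg: tuple[tuple[float, float], ...] = ((0.0, 0.0), (3.0, 0.0), (-3.0, 0.0), (0.0, 3.0), (0.0, -3.0))
    sound_speed_m_s: float = 1540.0
    sample_rate_hz: float = 4.0 * 7.81e6
    f_number: float | None = None  # None = no receive apodization

    def __post_init__(self) -> None:
        if len(self.angles_deg) < 1:
            raise ValueError("need at least one angle")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")


def _angle_direction(angle_deg: tuple[float, float]) -> np.ndarray:
    """Unit propagation direction (z, x, y) for (lateral, elevation) tilts."""
    a_lat, a_elev = (math.radians(a) for a in angle_deg)
    if abs(a_lat) >= math.pi / 2 or abs(a_elev) >= math.pi / 2:
        raise ValueError("tilt angle magnitudes must be < 90 degrees")
    ux, uy = math.sin(a_lat), math.sin(a_elev)
    uz_sq = 1.0 - ux * ux - uy * uy
    if uz_sq <= 0:
        raise ValueError("composite tilt exceeds 90 degrees")
    return np.array([math.sqrt(uz_sq), ux, uy])


def transmit_delay(
    voxel_mm: np.ndarray, angle_deg: tuple[float, float], sound_speed_m_s: float
) -> np.ndarray:
    """Plane-wave transmit delay (s) from the array plane to the voxel(s).

    ``voxel_mm`` is (..., 3) in (z, x, y) order.
    """
    u = _angle_direction(angle_deg)
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    return (voxel_mm @ u) * 1e-3 / sound_speed_m_s


def _interp_sample(trace: np.ndarray, sample_idx: np.ndarray) -> np.ndarray:
    """Linear inter-sample interpolation; out-of-range samples are zero."""
    n = trace.shape[-1]
    idx0 = np.floor(sample_idx).astype(int)
    frac = sample_idx - idx0
    valid = (idx0 >= 0) & (idx0 < n - 1)
    idx0c = np.clip(idx0, 0, n - 2)
    out = (1.0 - frac) * trace[idx0c] + frac * trace[idx0c + 1]
    out[~valid] = 0.0
    return out


def das_beamform(
    rf: RFDataSet, grid: ImagingGrid, scheme: PlaneWaveScheme | None = None
) -> list[VolumeSequence]:
    """Delay-and-sum each transmit angle onto the grid.

    Returns one single-frame :class:`VolumeSequence` per angle (callers
    stack frames across repeated acquisitions).  Voxel value is the sum
    over elements of the linearly interpolated channel sample at
    τ_tx + τ_rx; an optional f-number mask restricts receive elements to
    the acceptance cone.
    """
    if scheme is None:
        scheme = PlaneWaveScheme(
            angles_deg=tuple(rf.angles_deg),
            sound_speed_m_s=rf.sound_speed_m_s,
            sample_rate_hz=rf.sample_rate_hz,
        )
    c = scheme.sound_speed_m_s
    fs = scheme.sample_rate_hz
    elements = rf.probe.element_positions()

    zz, xx, yy = np.meshgrid(*grid.axes(), indexing="ij")
    voxels = np.stack([zz.ravel(), xx.ravel(), yy.ravel()], axis=1)

    out: list[VolumeSequence] = []
    for ai, angle in enumerate(rf.angles_deg):
        tau_tx = transmit_delay(voxels, angle, c)
        acc = np.zeros(voxels.shape[0], dtype=rf.data.dtype)
        for ei in range(elements.shape[0]):
            dist_mm = np.linalg.norm(voxels - elements[ei], axis=1)
            if scheme.f_number is not None:
                # Accept voxels within the element's f-number cone.
                lateral = np.linalg.norm(voxels[:, 1:] - elements[ei, 1:], axis=1)
                mask = voxels[:, 0] >= 2.0 * scheme.f_number * lateral
                if not mask.any():
                    continue
            else:
                mask = slice(None)
            tau = tau_tx + dist_mm * 1e-3 / c - rf.t0_s
            sample = _interp_sample(rf.data[ai, ei], tau * fs)
            if isinstance(mask, np.ndarray):
                acc[mask] += sample[mask]
            else:
                acc += sample
        if not np.any(acc):
            warnings.warn(f"angle {angle}: beamformed volume is all zeros "
                          "(grid may lie outside the insonified region)")
        vol = acc.reshape(grid.shape)
        out.append(VolumeSequence(vol[None], grid, frame_rate=1.0))
    return out


def compound(per_angle: list[VolumeSequence]) -> VolumeSequence:
    """Coherent mean across angles (grids and frame counts must match)."""
    if not per_angle:
        raise ValueError("no volumes to compound")
    g0 = per_angle[0].grid
    n0 = per_angle[0].n_frames
    for v in per_angle[1:]:
        if v.grid != g0 or v.n_frames != n0:
            raise ValueError("compound requires identical grids and frame counts")
    mean = np.mean([v.frames for v in per_angle], axis=0)
    return VolumeSequence(mean, g0, per_angle[0].frame_rate)


def envelope(seq: VolumeSequence, method: str = "auto") -> VolumeSequence:
    """Envelope detection.

    ``"hilbert"`` takes the magnitude of the analytic signal along the
    axial axis (for real RF-derived volumes); ``"abs"`` takes the plain
    magnitude (for complex data, or real data that is already an
    envelope); ``"auto"`` picks ``"abs"`` for complex or non-negative
    input and ``"hilbert"`` otherwise.
    """
    frames = seq.frames
    if method == "auto":
        if np.iscomplexobj(frames) or frames.min() >= 0:
            method = "abs"
        else:
            method = "hilbert"
    if method == "abs":
        env = np.abs(frames)
    elif method == "hilbert":
        env = np.abs(hilbert(frames.real, axis=1))
    else:
        raise ValueError(f"unknown envelope method {method!r}")
    return VolumeSequence(env, seq.grid, seq.frame_rate)


def write_rf(rf: RFDataSet, path) -> None:
    """Save an RF channel dataset to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        dset = f.create_dataset("rf", data=rf.data)
        dset.attrs["angles_deg"] = np.asarray(rf.angles_deg, dtype=float)
        dset.attrs["sample_rate_hz"] = rf.sample_rate_hz
        dset.attrs["sound_speed_m_s"] = rf.sound_speed_m_s
        dset.attrs["t0_s"] = rf.t0_s
        for name in ("n_elements_x", "n_elements_y", "pitch_mm",
                     "center_frequency_hz", "fractional_bandwidth"):
            dset.attrs[name] = getattr(rf.probe, name)


def read_rf(path) -> RFDataSet:
    """Load an RF channel dataset written by :func:`write_rf`."""
    import h5py

    from .core import FormatError

    with h5py.File(path, "r") as f:
        if "rf" not in f:
            raise FormatError(f"{path}: missing dataset 'rf'")
        dset = f["rf"]
        required = ("angles_deg", "sample_rate_hz", "sound_speed_m_s",
                    "n_elements_x", "n_elements_y", "pitch_mm",
                    "center_frequency_hz", "fractional_bandwidth")
        for attr in required:
            if attr not in dset.attrs:
                raise FormatError(f"{path}: missing attribute {attr!r}")
        probe = ProbeGeometry(
            n_elements_x=int(dset.attrs["n_elements_x"]),
            n_elements_y=int(dset.attrs["n_elements_y"]),
            pitch_mm=float(dset.attrs["pitch_mm"]),
            center_frequency_hz=float(dset.attrs["center_frequency_hz"]),
            fractional_bandwidth=float(dset.attrs["fractional_bandwidth"]),
        )
        return RFDataSet(
            data=dset[...],
            probe=probe,
            angles_deg=[tuple(a) for a in np.asarray(dset.attrs["angles_deg"])],
            sample_rate_hz=float(dset.attrs["sample_rate_hz"]),
            sound_speed_m_s=float(dset.attrs["sound_speed_m_s"]),
            t0_s=float(dset.attrs.get("t0_s", 0.0)),
        )
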