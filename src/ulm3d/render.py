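"""Super-resolved rendering and vessel measurements.

Smoothed tracks are rasterized onto an isotropic λ/20 grid: every voxel a
track segment passes through accumulates a visit count (intensity and
density) and the segment's signed axial velocity.  Dividing the velocity
accumulation by the density gives the mean axial velocity per voxel; a
median filter suppresses residual noisy tracks.  The low- and
high-threshold renderings are fused by averaging voxels where both are
non-zero, and measurement helpers size vessels (spline-interpolated FWHM)
and quantify bifurcation separability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .core import ImagingGrid
from .localize import Localization
from .track import Track

__all__ = [
    "SuperResVolume",
    "accumulate_tracks",
    "velocity_map",
    "fuse_passes",
    "final_smooth",
    "directional_split",
    "mip",
    "vessel_fwhm",
    "bifurcation_separation",
    "bubble_count_series",
]


@dataclass
class SuperResVolume:
    """λ/20-grid accumulations: visit counts and signed axial-velocity sums."""

    grid: ImagingGrid
    intensity: np.ndarray
    density: np.ndarray
    vz_sum: np.ndarray
    n_clipped: int = 0

    def __post_init__(self) -> None:
        for name in ("intensity", "density", "vz_sum"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if tuple(arr.shape) != tuple(self.grid.shape):
                raise ValueError(f"{name} shape {arr.shape} != grid shape {self.grid.shape}")
            setattr(self, name, arr)


def _segment_voxels(p0_idx: np.ndarray, p1_idx: np.ndarray) -> np.ndarray:
    """Voxel indices of the exact 3-D digital line from p0 to p1.

    The digital line is the set of nearest-voxel roundings of the
    continuous segment.  Evaluating the segment at the midpoints between
    successive half-integer boundary crossings (per axis) enumerates that
    set exactly, with no sampling-density parameter.
    """
    d = p1_idx - p0_idx
    ts = [0.0, 1.0]
    for axis in range(3):
        if d[axis] == 0:
            continue
        lo, hi = sorted((p0_idx[axis], p1_idx[axis]))
        # half-integer planes crossed by this axis
        first = math.floor(lo + 0.5) + 0.5
        k = first
        while k < hi:
            ts.append((k - p0_idx[axis]) / d[axis])
            k += 1.0
    ts = np.clip(np.unique(ts), 0.0, 1.0)
    mids = (ts[:-1] + ts[1:]) / 2.0
    pts = np.concatenate([p0_idx[None], p0_idx[None] + mids[:, None] * d[None], p1_idx[None]])
    vox = np.round(pts).astype(int)
    keep = np.ones(len(vox), dtype=bool)
    keep[1:] = np.any(np.diff(vox, axis=0) != 0, axis=1)
    vox = vox[keep]
    _, first_idx = np.unique(vox, axis=0, return_index=True)
    return vox[np.sort(first_idx)]


def accumulate_tracks(tracks: list[Track], grid: ImagingGrid) -> SuperResVolume:
    """Rasterize track segments onto the grid.

    Every voxel on the digital line between consecutive smoothed positions
    gets intensity += 1, density += 1 and vz_sum += the segment's signed
    axial velocity.  Voxels falling outside the grid are clipped and
    counted in ``n_clipped``.
    """
    shape = np.asarray(grid.shape)
    intensity = np.zeros(grid.shape)
    density = np.zeros(grid.shape)
    vz_sum = np.zeros(grid.shape)
    n_clipped = 0
    for t in tracks:
        pos = t.smoothed_mm if t.smoothed_mm is not None else t.positions_mm
        vz = t.vz_mm_s if t.vz_mm_s is not None else np.zeros(max(len(t) - 1, 0))
        idx = grid.mm_to_index(pos)
        for i in range(len(pos) - 1):
            vox = _segment_voxels(idx[i], idx[i + 1])
            inside = np.all((vox >= 0) & (vox < shape), axis=1)
            n_clipped += int(np.count_nonzero(~inside))
            vox = vox[inside]
            if not len(vox):
                continue
            flat = tuple(vox.T)
            np.add.at(intensity, flat, 1.0)
            np.add.at(density, flat, 1.0)
            np.add.at(vz_sum, flat, vz[i])
    if n_clipped:
        warnings.warn(f"accumulate_tracks: {n_clipped} voxel visits fell outside the grid")
    return SuperResVolume(grid, intensity, density, vz_sum, n_clipped)


def velocity_map(vol: SuperResVolume, median_kernel: int = 3) -> np.ndarray:
    """Mean axial velocity per voxel, median-filtered.

    vz = vz_sum / density where density > 0, else 0; then a 3-D median
    filter of the given odd kernel size removes isolated noisy-track
    voxels.
    """
    vz = np.zeros(vol.grid.shape)
    mask = vol.density > 0
    vz[mask] = vol.vz_sum[mask] / vol.density[mask]
    if median_kernel and median_kernel > 1:
        vz = ndimage.median_filter(vz, size=median_kernel, mode="nearest")
    return vz


def fuse_passes(volume_low: np.ndarray, volume_high: np.ndarray) -> np.ndarray:
    """Combine the two pass renderings.

    Voxelwise: mean where both are non-zero, the single value where only
    one is — so vasculature seen by both passes is not rendered twice as
    bright as vasculature seen by one.
    """
    a = np.asarray(volume_low, dtype=float)
    b = np.asarray(volume_high, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    both = (a != 0) & (b != 0)
    out = a + b
    out[both] = 0.5 * (a[both] + b[both])
    return out


def final_smooth(volume: np.ndarray, sigma: float = 0.8) -> np.ndarray:
    """Isotropic Gaussian blur, σ in voxels (cosmetic final step)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.asarray(volume, dtype=float).copy()
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma)


def directional_split(vz: np.ndarray, percentile: float = 99.9):
    """Split a signed axial-velocity volume by flow direction.

    Returns (positive-flow volume, negative-flow volume, saturation
    limit), where the limit is the ``percentile`` of |vz| over non-zero
    voxels — the color-map saturation bound that still represents 99.9% of
    detected velocity magnitudes.
    """
    vz = np.asarray(vz, dtype=float)
    pos = np.where(vz > 0, vz, 0.0)
    neg = np.where(vz < 0, vz, 0.0)
    nz = np.abs(vz[vz != 0])
    saturation = float(np.percentile(nz, percentile)) if nz.size else 0.0
    return pos, neg, saturation


def mip(volume: np.ndarray, axis: int | str, mode: str = "max",
        slab: tuple[int, int] | None = None) -> np.ndarray:
    """Maximum (or minimum) intensity projection along an axis.

    ``axis`` may be 0/1/2 or 'z'/'x'/'y'.  ``slab=(start, stop)`` limits
    the projection to a section of slices (e.g. a thin coronal slab).
    """
    volume = np.asarray(volume)
    if isinstance(axis, str):
        axis = {"z": 0, "x": 1, "y": 2}[axis]
    if slab is not None:
        volume = np.take(volume, range(slab[0], slab[1]), axis=axis)
    if mode == "max":
        return volume.max(axis=axis)
    if mode == "min":
        return volume.min(axis=axis)
    raise ValueError("mode must be 'max' or 'min'")


def _upsample_profile(profile: np.ndarray, spacing_mm: float, factor: int = 10):
    x = np.arange(len(profile)) * spacing_mm
    spline = CubicSpline(x, profile)
    xf = np.linspace(x[0], x[-1], (len(profile) - 1) * factor + 1)
    return xf, spline(xf)


def _significant_peaks(yf: np.ndarray) -> np.ndarray:
    """Indices of local maxima at least half as tall as the global max."""
    interior = (yf[1:-1] >= yf[:-2]) & (yf[1:-1] > yf[2:])
    peaks = np.flatnonzero(interior) + 1
    return peaks[yf[peaks] >= 0.5 * yf.max()]


def vessel_fwhm(profile: np.ndarray, spacing_mm: float, upsample: int = 10) -> float:
    """Full width at half maximum of a single-peak cross-section, in µm.

    The profile is cubic-spline interpolated (×10 by default) and the
    width is measured between the half-maximum crossings bracketing the
    dominant peak.  Profiles with more than one comparable peak, or
    without two crossings, are rejected.
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) < 4:
        raise ValueError("profile too short")
    xf, yf = _upsample_profile(profile, spacing_mm, upsample)
    peaks = _significant_peaks(yf)
    if len(peaks) != 1:
        raise ValueError(f"profile must have a single dominant peak, found {len(peaks)}")
    peak = peaks[0]
    half = yf[peak] / 2.0
    below_left = np.flatnonzero(yf[:peak] < half)
    below_right = np.flatnonzero(yf[peak:] < half)
    if not len(below_left) or not len(below_right):
        raise ValueError("no half-maximum crossing on one side; width undefined")
    i = below_left[-1]
    left = xf[i] + (xf[i + 1] - xf[i]) * (half - yf[i]) / (yf[i + 1] - yf[i])
    j = peak + below_right[0] - 1
    right = xf[j] + (xf[j + 1] - xf[j]) * (half - yf[j]) / (yf[j + 1] - yf[j])
    return float((right - left) * 1e3)


def bifurcation_separation(profile: np.ndarray, spacing_mm: float,
                           upsample: int = 10) -> tuple[float, float]:
    """Separability of a two-peak cross-section.

    Returns ``(threshold, gap_um)``: the valley intensity between the two
    peaks — the minimum threshold above which they form disjoint
    supra-threshold components — and the peak-to-peak distance in µm.
    Raises if the profile does not show two distinct peaks.
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) < 4:
        raise ValueError("profile too short")
    xf, yf = _upsample_profile(profile, spacing_mm, upsample)
    peaks = _significant_peaks(yf)
    if len(peaks) < 2:
        raise ValueError("profile does not show two separable peaks")
    # Use the two tallest significant peaks.
    order = peaks[np.argsort(yf[peaks])[::-1][:2]]
    p0, p1 = np.sort(order)
    valley = float(yf[p0:p1 + 1].min())
    if valley >= min(yf[p0], yf[p1]):
        raise ValueError("peaks are merged; no separating threshold exists")
    gap_um = float((xf[p1] - xf[p0]) * 1e3)
    return valley, gap_um


def bubble_count_series(
    locs: list[Localization] | np.ndarray,
    n_frames: int,
    block: int = 200,
    window: int = 5,
):
    """Bubbles-per-volume time series with block statistics.

    Returns a dict with per-frame ``counts``, per-200-frame ``block_means``
    and ``block_stds``, and the ``smoothed`` 5-point moving average of the
    block means (edges use the available shorter window).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if isinstance(locs, np.ndarray):
        counts = np.asarray(locs, dtype=float)
    else:
        counts = np.zeros(n_frames)
        for l in locs:
            if 0 <= l.frame < n_frames:
                counts[l.frame] += 1
    n_blocks = len(counts) // block
    block_means = np.array([counts[i * block:(i + 1) * block].mean() for i in range(n_blocks)])
    block_stds = np.array([counts[i * block:(i + 1) * block].std() for i in range(n_blocks)])
    half = window // 2
    smoothed = np.array([
        block_means[max(0, i - half):i + half + 1].mean() for i in range(n_blocks)
    ])
    return {
        "counts": counts,
        "block_means": block_means,
        "block_stds": block_stds,
        "smoothed": smoothed,
    }
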