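"""Sub-voxel microbubble localization.

Per frame: normalize and noise-threshold the envelope, convolve with a
PSF-matched Gaussian, segment blobs by a mean + k·std intensity threshold,
and take the intensity-weighted centroid of each blob.  The whole chain is
run twice — once with a low segmentation threshold that keeps dim bubbles
and once with a high threshold that separates densely packed bright
bubbles — and the two passes are fused downstream at the rendering stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImagingGrid, VolumeSequence
from .synth import PSFModel

__all__ = [
    "LocalizeConfig",
    "Localization",
    "noise_threshold",
    "match_filter",
    "segment",
    "weighted_centroid",
    "localize_pass",
    "dual_pass_localize",
    "localizations_to_frame",
    "read_localizations",
    "write_localizations",
]

FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ≈ 2.355

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class LocalizeConfig:
    """Thresholds and kernel for one localization pass.

    ``noise_threshold_frac`` — fraction of the per-frame maximum below
    which voxels are zeroed (empirically 1–7%).  ``segment_k_std`` —
    blob segmentation threshold in standard deviations above the mean
    (empirically 1–4; low pass 1.5, high pass 3.5).
    """

    noise_threshold_frac: float = 0.03
    segment_k_std: float = 1.5
    psf: PSFModel = field(default_factory=PSFModel.from_frequency)
    connectivity: int = 26
    min_blob_voxels: int = 2
    centroid_weights: str = "convolved"  # or "raw"

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_threshold_frac < 1.0):
            raise ValueError("noise_threshold_frac must be in [0, 1)")
        if self.segment_k_std <= 0:
            raise ValueError("segment_k_std must be positive")
        if self.connectivity not in _CONNECTIVITY:
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.centroid_weights not in {"convolved", "raw"}:
            raise ValueError("centroid_weights must be 'convolved' or 'raw'")


@dataclass(frozen=True)
class Localization:
    """One sub-voxel bubble detection."""

    frame: int
    position_mm: tuple[float, float, float]
    intensity: float
    pass_label: str = "low"
    on_border: bool = False


def noise_threshold(volume: np.ndarray, frac: float) -> np.ndarray:
    """Normalize to max 1 and zero voxels below ``frac`` of the maximum."""
    volume = np.asarray(volume, dtype=float)
    vmax = volume.max() if volume.size else 0.0
    if vmax <= 0:
        warnings.warn("noise_threshold: all-zero volume, returned unchanged")
        return volume.copy()
    out = volume / vmax
    out[out < frac] = 0.0
    return out


def _gaussian_kernel_1d(sigma_vox: float) -> np.ndarray:
    half = max(1, int(math.ceil(3.0 * sigma_vox)))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_vox) ** 2)
    return k / k.sum()


def match_filter(volume: np.ndarray, psf: PSFModel, spacing_mm) -> np.ndarray:
    """Convolve with the unit-sum anisotropic Gaussian matched to the PSF.

    σ per axis = FWHM / 2.355 (in voxels, given the grid spacing); kernel
    half-width 3σ; reflective boundaries.  Separable, so applied as three
    1-D convolutions whose unit sums multiply to a unit-sum 3-D kernel.
    """
    out = np.asarray(volume, dtype=float)
    spacing = np.asarray(spacing_mm, dtype=float)
    for axis, fwhm in enumerate(psf.fwhm_mm):
        sigma_vox = fwhm / FWHM_TO_SIGMA / spacing[axis]
        out = ndimage.convolve1d(out, _gaussian_kernel_1d(sigma_vox), axis=axis, mode="reflect")
    return out


def segment(volume: np.ndarray, k_std: float, connectivity: int = 26,
            min_blob_voxels: int = 2) -> tuple[np.ndarray, int]:
    """Label connected supra-threshold blobs.

    Threshold = mean + k_std × std, both over the whole volume.  Blobs with
    fewer than ``min_blob_voxels`` voxels are dropped (labels stay dense).
    Returns ``(labels, n_blobs)``.
    """
    if k_std <= 0:
        raise ValueError("k_std must be positive")
    volume = np.asarray(volume, dtype=float)
    mask = volume > volume.mean() + k_std * volume.std()
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n = ndimage.label(mask, structure=structure)
    if n and min_blob_voxels > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_blob_voxels)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
            remap = np.zeros(n + 1, dtype=labels.dtype)
            kept = np.setdiff1d(np.arange(1, n + 1), small)
            remap[kept] = np.arange(1, kept.size + 1)
            labels = remap[labels]
            n = kept.size
    return labels, int(n)


def weighted_centroid(indices: np.ndarray, weights: np.ndarray, grid: ImagingGrid) -> np.ndarray:
    """Intensity-weighted mean position in mm (voxel-center coordinates)."""
    indices = np.atleast_2d(np.asarray(indices, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if indices.shape[0] == 0:
        raise ValueError("blob is empty")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("blob has zero total weight")
    centroid_idx = (indices * weights[:, None]).sum(axis=0) / total
    return grid.index_to_mm(centroid_idx)


def _localize_volume(
    volume: np.ndarray, grid: ImagingGrid, config: LocalizeConfig, frame: int, pass_label: str
) -> list[Localization]:
    thresholded = noise_threshold(volume, config.noise_threshold_frac)
    convolved = match_filter(thresholded, config.psf, grid.spacing_mm)
    labels, n = segment(convolved, config.segment_k_std, config.connectivity,
                        config.min_blob_voxels)
    if n == 0:
        return []
    weights_vol = convolved if config.centroid_weights == "convolved" else thresholded
    out: list[Localization] = []
    shape = np.asarray(volume.shape)
    objects = ndimage.find_objects(labels)
    for label, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        local = labels[slc] == label
        idx = np.argwhere(local)
        idx += np.array([s.start for s in slc])
        w = weights_vol[tuple(idx.T)]
        total = w.sum()
        if total <= 0:
            continue  # zero-weight blob: discard
        pos = weighted_centroid(idx, w, grid)
        on_border = bool(np.any(idx == 0) or np.any(idx == shape - 1))
        out.append(
            Localization(
                frame=frame,
                position_mm=tuple(float(v) for v in pos),
                intensity=float(total),
                pass_label=pass_label,
                on_border=on_border,
            )
        )
    return out


def localize_pass(
    seq: VolumeSequence, config: LocalizeConfig, pass_label: str = "low"
) -> list[Localization]:
    """Run the full localization chain independently on every frame."""
    out: list[Localization] = []
    for frame in range(seq.n_frames):
        out.extend(_localize_volume(seq.frames[frame], seq.grid, config, frame, pass_label))
    return out


def dual_pass_localize(
    seq: VolumeSequence, low: LocalizeConfig, high: LocalizeConfig
) -> tuple[list[Localization], list[Localization]]:
    """Run the low- and high-threshold passes; fusion happens at render time."""
    if low.segment_k_std > high.segment_k_std:
        raise ValueError("low pass must not use a larger segment_k_std than the high pass")
    return (
        localize_pass(seq, low, pass_label="low"),
        localize_pass(seq, high, pass_label="high"),
    )


def localizations_to_frame(locs: list[Localization]) -> pd.DataFrame:
    rows = [
        (l.pass_label, l.frame, *l.position_mm, l.intensity, l.on_border) for l in locs
    ]
    return pd.DataFrame(
        rows, columns=["pass", "frame", "z_mm", "x_mm", "y_mm", "intensity", "on_border"]
    )


def write_localizations(locs: list[Localization], path: str | Path) -> None:
    localizations_to_frame(locs).to_csv(path, index=False)


def read_localizations(path: str | Path) -> list[Localization]:
    df = pd.read_csv(path)
    return [
        Localization(
            frame=int(r["frame"]),
            position_mm=(float(r["z_mm"]), float(r["x_mm"]), float(r["y_mm"])),
            intensity=float(r["intensity"]),
            pass_label=str(r["pass"]),
            on_border=bool(r.get("on_border", False)),
        )
        for r in df.to_dict("records")
    ]
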