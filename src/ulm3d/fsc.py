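"""Single-volume Fourier shell correlation (FSC) resolution estimation.

A single super-resolved volume is split into four sub-volumes by 2×2
checkerboard decimation along the lateral and elevation axes; the FSC is
computed for the two complementary pairs and the two curves averaged.  The
resolution is the inverse of the first frequency at which the averaged
curve drops below the shell-size-dependent 1/2-bit information threshold.
Because the decimated grids are offset by one original voxel, a phase-ramp
correction for the known sub-voxel shift is applied before correlating, so
identical content yields FSC ≡ 1 on every shell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FSCCurve",
    "split_four",
    "fsc_curve",
    "half_bit_threshold",
    "single_image_fsc",
]

#: Sentinel resolution when the curve never drops below threshold.
BEYOND_NYQUIST = float("inf")


@dataclass
class FSCCurve:
    """FSC per spherical frequency shell plus the derived resolution."""

    shell_frequencies_per_um: np.ndarray
    correlation: np.ndarray
    n_voxels_per_shell: np.ndarray
    threshold_curve: np.ndarray | None = None
    resolution_um: float | None = None

    def __post_init__(self) -> None:
        self.shell_frequencies_per_um = np.asarray(self.shell_frequencies_per_um, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.n_voxels_per_shell = np.asarray(self.n_voxels_per_shell, dtype=int)


def split_four(
    volume: np.ndarray, axes: tuple[int, int] = (1, 2)
) -> tuple[list[np.ndarray], list[tuple[int, ...]]]:
    """2×2 checkerboard decimation along two axes.

    Returns ``(subvolumes, offsets)`` in the order ee, oo, eo, oe where
    e/o denote even/odd original indices along the two split axes; the
    complementary FSC pairs are (ee, oo) and (eo, oe).  ``offsets`` give
    each sub-volume's origin shift in *original* voxels.  Odd-length axes
    are trimmed by one sample.  The sub-volume spacing doubles along the
    split axes.
    """
    volume = np.asarray(volume)
    a0, a1 = axes
    trim = [slice(None)] * volume.ndim
    for ax in axes:
        n = volume.shape[ax]
        if n % 2:
            trim[ax] = slice(0, n - 1)
    volume = volume[tuple(trim)]

    def pick(o0: int, o1: int) -> np.ndarray:
        sl = [slice(None)] * volume.ndim
        sl[a0] = slice(o0, None, 2)
        sl[a1] = slice(o1, None, 2)
        return volume[tuple(sl)]

    subs = [pick(0, 0), pick(1, 1), pick(0, 1), pick(1, 0)]
    offsets = []
    for o0, o1 in ((0, 0), (1, 1), (0, 1), (1, 0)):
        off = [0] * volume.ndim
        off[a0], off[a1] = o0, o1
        offsets.append(tuple(off))
    return subs, offsets


def _freq_grids(shape, spacing_mm):
    return np.meshgrid(
        *[np.fft.fftfreq(n, d=d) for n, d in zip(shape, spacing_mm)], indexing="ij"
    )


def _shell_index(shape, spacing_mm):
    """Shell assignment (one DFT bin wide) and shell center frequencies (1/mm)."""
    grids = _freq_grids(shape, spacing_mm)
    radius = np.sqrt(sum(g**2 for g in grids))
    df = max(1.0 / (n * d) for n, d in zip(shape, spacing_mm))
    # Shells extend to the finest axis' Nyquist: with anisotropic sampling
    # the outer shells are only partially supported (they draw on the
    # finer-sampled axes), but they carry real signal and are what lets the
    # measured resolution go beyond the coarser axes' Nyquist.
    f_nyquist = max(1.0 / (2.0 * d) for d in spacing_mm)
    n_shells = int(math.floor(f_nyquist / df)) + 1
    shell = np.round(radius / df).astype(int)
    return shell, n_shells, df


def fsc_curve(
    v1: np.ndarray,
    v2: np.ndarray,
    spacing_mm,
    shift_mm=None,
) -> FSCCurve:
    """FSC between two volumes sampled with the same spacing.

    FSC(r) = Re[Σ_shell F1·conj(F2)] / √(Σ_shell |F1|²·Σ_shell |F2|²) over
    shells one DFT frequency bin wide around the DC-centered radius.
    ``shift_mm`` is the physical offset of v2's sample grid relative to
    v1's; when given, the corresponding phase ramp is removed from F2 so
    the shift does not depress high-frequency correlation.  Empty shells
    are dropped.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(f"shape mismatch {v1.shape} vs {v2.shape}")
    spacing_mm = tuple(float(s) for s in spacing_mm)

    f1 = np.fft.fftn(v1)
    f2 = np.fft.fftn(v2)
    if shift_mm is not None and any(s != 0 for s in shift_mm):
        grids = _freq_grids(v1.shape, spacing_mm)
        phase = sum(g * s for g, s in zip(grids, shift_mm))
        f2 = f2 * np.exp(-2j * np.pi * phase)

    shell, n_shells, df = _shell_index(v1.shape, spacing_mm)
    flat = shell.ravel()
    keep = flat < n_shells
    flat = flat[keep]

    cross = np.bincount(flat, weights=(f1 * np.conj(f2)).real.ravel()[keep], minlength=n_shells)
    p1 = np.bincount(flat, weights=(np.abs(f1) ** 2).ravel()[keep], minlength=n_shells)
    p2 = np.bincount(flat, weights=(np.abs(f2) ** 2).ravel()[keep], minlength=n_shells)
    counts = np.bincount(flat, minlength=n_shells)

    nonempty = (counts > 0) & (p1 > 0) & (p2 > 0)
    corr = np.zeros(n_shells)
    corr[nonempty] = cross[nonempty] / np.sqrt(p1[nonempty] * p2[nonempty])

    freqs_per_mm = np.arange(n_shells) * df
    return FSCCurve(
        shell_frequencies_per_um=freqs_per_mm[nonempty] / 1e3,
        correlation=corr[nonempty],
        n_voxels_per_shell=counts[nonempty],
    )


def half_bit_threshold(n_voxels_per_shell: np.ndarray) -> np.ndarray:
    """1/2-bit information threshold per shell.

    T(n) = (0.2071 + 1.9102/√n) / (1.2071 + 0.9102/√n); decreasing in n
    with asymptote 0.2071/1.2071 ≈ 0.1716.
    """
    n = np.asarray(n_voxels_per_shell, dtype=float)
    if np.any(n < 1):
        raise ValueError("shell voxel counts must be >= 1")
    rn = 1.0 / np.sqrt(n)
    return (0.2071 + 1.9102 * rn) / (1.2071 + 0.9102 * rn)


def _first_crossing(
    freqs_per_um: np.ndarray,
    corr: np.ndarray,
    threshold: np.ndarray,
    spike_tolerance: int = 1,
) -> float:
    """Resolution (µm) from the first sustained drop below threshold.

    The curve must first be above threshold (DC shell); a dip of at most
    ``spike_tolerance`` shells followed by at least two shells back above
    the threshold is ignored.
    """
    armed = False
    i = 0
    n = len(corr)
    while i < n:
        if not armed:
            if corr[i] >= threshold[i]:
                armed = True
            i += 1
            continue
        if corr[i] >= threshold[i]:
            i += 1
            continue
        # candidate crossing at i: check the spike-tolerance rule
        dip_end = i
        while dip_end < n and corr[dip_end] < threshold[dip_end]:
            dip_end += 1
        dip_len = dip_end - i
        recovery = 0
        j = dip_end
        while j < n and corr[j] >= threshold[j]:
            recovery += 1
            j += 1
        if dip_len <= spike_tolerance and recovery >= 2:
            i = dip_end  # transient dip: ignore
            continue
        if freqs_per_um[i] <= 0:
            return BEYOND_NYQUIST
        return 1.0 / freqs_per_um[i]
    return BEYOND_NYQUIST


def single_image_fsc(
    volume: np.ndarray,
    spacing_mm,
    axes: tuple[int, int] = (1, 2),
    spike_tolerance: int = 1,
) -> FSCCurve:
    """Single-image FSC with the 1/2-bit criterion.

    Splits the volume into four checkerboard sub-volumes along ``axes``
    (lateral and elevation by default), computes the FSC of the two
    complementary pairs on the doubled sub-volume spacing, averages the
    two curves, and intersects with the 1/2-bit threshold.  The reported
    resolution is in physical µm; when the averaged curve never drops
    below threshold the resolution is the ``inf`` beyond-Nyquist sentinel.
    """
    spacing_mm = tuple(float(s) for s in spacing_mm)
    sub_spacing = tuple(
        s * 2.0 if a in axes else s for a, s in enumerate(spacing_mm)
    )
    subs, offsets = split_four(volume, axes)
    curves = []
    for (ia, ib) in ((0, 1), (2, 3)):
        shift = tuple(
            (offsets[ib][a] - offsets[ia][a]) * spacing_mm[a] for a in range(volume.ndim)
        )
        curves.append(fsc_curve(subs[ia], subs[ib], sub_spacing, shift_mm=shift))
    f0, f1 = curves
    if len(f0.correlation) != len(f1.correlation) or not np.allclose(
        f0.shell_frequencies_per_um, f1.shell_frequencies_per_um
    ):
        raise ValueError("sub-volume pairs produced mismatched shells")
    corr = 0.5 * (f0.correlation + f1.correlation)
    counts = f0.n_voxels_per_shell
    threshold = half_bit_threshold(counts)
    resolution = _first_crossing(
        f0.shell_frequencies_per_um, corr, threshold, spike_tolerance
    )
    return FSCCurve(
        shell_frequencies_per_um=f0.shell_frequencies_per_um,
        correlation=corr,
        n_voxels_per_shell=counts,
        threshold_curve=threshold,
        resolution_um=resolution,
    )
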