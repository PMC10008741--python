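"""Block-wise SVD clutter filtering.

Tissue and skull echoes are bright but temporally coherent, so in the
space × time Casorati matrix of a volume block they concentrate in the
largest singular components; microbubbles, which move between frames,
spread across the spectrum.  Zeroing the top singular values therefore
suppresses clutter while retaining bubble signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core import VolumeSequence

__all__ = ["SVDConfig", "casorati", "uncasorati", "svd_clutter_filter", "svd_filter_sequence"]


@dataclass(frozen=True)
class SVDConfig:
    """``block_size`` frames per batch; ``removed_fraction`` of the largest
    singular values (counted against the temporal dimension, ceiling
    rounding — 15% of a 200-frame block removes exactly 30) zeroed."""

    block_size: int = 200
    removed_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if not (0.0 <= self.removed_fraction < 1.0):
            raise ValueError("removed_fraction must be in [0, 1)")

    def n_removed(self, n_frames: int) -> int:
        return math.ceil(self.removed_fraction * n_frames)


def casorati(block: np.ndarray) -> np.ndarray:
    """Reshape a (t, z, x, y) block into a (space, time) Casorati matrix.

    Column t is frame t flattened in C-order (z, then x, then y fastest).
    """
    block = np.asarray(block)
    if block.ndim != 4 or block.shape[0] < 1:
        raise ValueError("block must be a non-empty (t, z, x, y) array")
    return block.reshape(block.shape[0], -1).T


def uncasorati(matrix: np.ndarray, spatial_shape: tuple[int, int, int]) -> np.ndarray:
    """Exact inverse of :func:`casorati`."""
    return np.ascontiguousarray(matrix.T).reshape((matrix.shape[1],) + tuple(spatial_shape))


def svd_clutter_filter(block: np.ndarray, config: SVDConfig | None = None) -> np.ndarray:
    """Zero the K largest singular values of the block's Casorati matrix.

    K = ceil(removed_fraction × n_frames).  Output has the input's shape
    and dtype class (complex stays complex).  Energy can only decrease
    (orthogonal projection) and the output rank is at most n_frames − K.
    """
    if config is None:
        config = SVDConfig()
    block = np.asarray(block)
    if block.ndim != 4 or block.shape[0] < 2:
        raise ValueError("block must have at least 2 frames")
    n_t = block.shape[0]
    k = config.n_removed(n_t)
    if k == 0:
        return block.copy()
    mat = casorati(block)
    u, s, vh = linalg.svd(mat, full_matrices=False)
    s = s.copy()
    s[:k] = 0.0
    filtered = (u * s) @ vh
    return uncasorati(filtered, block.shape[1:])


def svd_filter_sequence(seq: VolumeSequence, config: SVDConfig | None = None) -> VolumeSequence:
    """Filter a sequence independently per non-overlapping block.

    A short trailing remainder (≥ 2 frames) is filtered as its own block
    with K scaled to its length; a single trailing frame is zeroed, since
    no temporal separation is possible for it.
    """
    if config is None:
        config = SVDConfig()
    frames = seq.frames
    out = np.empty_like(frames)
    t = 0
    while t < frames.shape[0]:
        stop = min(t + config.block_size, frames.shape[0])
        if stop - t >= 2:
            out[t:stop] = svd_clutter_filter(frames[t:stop], config)
        else:
            out[t:stop] = 0.0
        t = stop
    return VolumeSequence(out, seq.grid, seq.frame_rate)
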