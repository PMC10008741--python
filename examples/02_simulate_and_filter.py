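"""Generate a synthetic bubble scene and remove the clutter by SVD.

Builds a branching vessel tree with Poiseuille bubble flow, renders it to
an envelope sequence with bright quasi-static clutter on a λ/2 grid, then
shows how much of the clutter the singular-value filter removes while the
moving bubbles survive.
"""

import numpy as np

from ulm3d import beamform as bf
from ulm3d import clutterfilt, synth

tree, truth, seq, grid, psf = synth.make_demo_scene(seed=0, n_frames=200)
print(f"vessel tree: {len(tree)} segments, "
      f"{sum(s.length_mm for s in tree):.1f} mm total length")
print(f"scene: {seq.n_frames} frames of {grid.shape} voxels at "
      f"{seq.frame_rate:.0f} volumes/s, ~{truth.counts_per_frame().mean():.1f} "
      "bubbles in view")

cfg = clutterfilt.SVDConfig(block_size=200, removed_fraction=0.15)
print(f"\nSVD filter: removing {cfg.n_removed(cfg.block_size)} of "
      f"{cfg.block_size} singular values per block")
filtered = clutterfilt.svd_filter_sequence(seq, cfg)
env = bf.envelope(filtered, method="abs")

# clutter dominates the raw frames; after filtering the bubbles do
frame = 100
raw_peak = seq.frames[frame].max()
bubble_voxels = np.round(grid.mm_to_index(truth.positions(frame))).astype(int)
bubble_voxels = np.clip(bubble_voxels, 0, np.array(grid.shape) - 1)
at_bubbles = env.frames[frame][tuple(bubble_voxels.T)]
print(f"raw frame peak (clutter-dominated):    {raw_peak:8.1f}")
print(f"filtered frame peak:                   {env.frames[frame].max():8.2f}")
print(f"filtered intensity at true bubbles:    median {np.median(at_bubbles):.2f}")
print(f"filtered background median:            {np.median(env.frames[frame]):.4f}")
# Bubbles (unit-to-10× amplitude) now stand out against a background that
# started ~30 dB above them.
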