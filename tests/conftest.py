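"""Shared fixtures.

The expensive end-to-end artefacts (recovery scene, two-vessel phantom)
are session-scoped so the acceptance tests and the unit tests that need a
realistic scene share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from ulm3d import beamform as bf
from ulm3d import clutterfilt, localize, metrics, render, synth, track
from ulm3d.core import ImagingGrid, wavelength_um

LAMBDA_MM = wavelength_um(7.81e6) * 1e-3


@pytest.fixture(scope="session")
def recovery_chain():
    """Parallel-vessel recovery scene run through localization + tracking.

    32×48×48 λ/2 grid, 500 frames at 500 vps, ~20 bubbles in view on the
    vessel centerlines at 20 mm/s; dual-pass localization and tracking of
    the low pass.
    """
    tree, truth, seq, grid, psf = synth.make_parallel_vessel_scene(seed=0, n_frames=500)
    low = localize.LocalizeConfig(segment_k_std=1.5, psf=psf)
    high = localize.LocalizeConfig(segment_k_std=3.5, psf=psf)
    locs_low, locs_high = localize.dual_pass_localize(seq, low, high)
    tracks_low = track.link_tracks(locs_low, seq.frame_rate)
    return {
        "tree": tree,
        "truth": truth,
        "seq": seq,
        "grid": grid,
        "psf": psf,
        "locs_low": locs_low,
        "locs_high": locs_high,
        "tracks_low": tracks_low,
    }


@pytest.fixture(scope="session")
def two_vessel_chain():
    """Full chain (clutter → SVD → localize → track) on the 60 µm phantom."""
    # sparse bubbles over a long acquisition: cross-vessel PSF-merged
    # localizations scale with density², vessel coverage only with
    # density × duration, so this regime keeps the inter-vessel valley open
    tree = synth.make_two_vessel_tree(separation_mm=0.060, peak_speed_mm_s=30.0)
    truth = synth.simulate_bubbles(
        tree, duration_s=4.0, frame_rate=500.0, mean_bubbles_in_view=1.2,
        seed=3, radial_mode="centerline",
    )
    spacing = LAMBDA_MM / 2.0
    grid = ImagingGrid(
        (1.5 - 16 * spacing, -24 * spacing, -24 * spacing), (spacing,) * 3, (32, 48, 48)
    )
    psf = synth.PSFModel.from_frequency()
    noise = synth.SceneNoiseModel(noise_std=0.02, seed=4)
    seq = synth.render_bmode(truth, psf, noise, grid)
    env = bf.envelope(
        clutterfilt.svd_filter_sequence(seq, clutterfilt.SVDConfig(200, 0.15)), "abs"
    )
    locs_low, locs_high = localize.dual_pass_localize(
        env,
        localize.LocalizeConfig(segment_k_std=1.5, psf=psf),
        localize.LocalizeConfig(segment_k_std=3.5, psf=psf),
    )
    tracks_low = track.link_tracks(locs_low, 500.0)
    tracks_high = track.link_tracks(locs_high, 500.0)
    return {
        "tree": tree,
        "grid": grid,
        "tracks_low": tracks_low,
        "tracks_high": tracks_high,
    }


@pytest.fixture(scope="session")
def recovery_metrics(recovery_chain):
    res = metrics.localization_errors(
        recovery_chain["truth"],
        recovery_chain["locs_low"] + recovery_chain["locs_high"],
        recovery_chain["grid"],
        recovery_chain["psf"],
    )
    speed = metrics.speed_recovery(recovery_chain["tracks_low"], recovery_chain["truth"])
    return {"loc": res, "speed": speed}


@pytest.fixture(scope="session")
def dense_render():
    """Raw λ/20 accumulation of full-chain tracks on the branching tree.

    Poiseuille radial offsets fill the vessel lumina, so the rendering has
    stochastic fine-scale texture — the regime where the single-image FSC
    yields a finite resolution.
    """
    tree, truth, seq, grid, psf = synth.make_demo_scene(
        seed=0, n_frames=500, radial_mode="poiseuille"
    )
    env = bf.envelope(
        clutterfilt.svd_filter_sequence(seq, clutterfilt.SVDConfig(200, 0.15)), "abs"
    )
    locs_low, locs_high = localize.dual_pass_localize(
        env,
        localize.LocalizeConfig(segment_k_std=1.5, psf=psf),
        localize.LocalizeConfig(segment_k_std=3.5, psf=psf),
    )
    tracks_low = track.link_tracks(locs_low, seq.frame_rate)
    tracks_high = track.link_tracks(locs_high, seq.frame_rate)
    sp20 = LAMBDA_MM / 20.0
    sr = ImagingGrid((0.0, -2.1, -1.6), (sp20,) * 3, (320, 310, 320))
    fused = render.fuse_passes(
        render.accumulate_tracks(tracks_low, sr).intensity,
        render.accumulate_tracks(tracks_high, sr).intensity,
    )
    return fused, sr
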