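"""End-to-end pipeline orchestration.

simulate → [beamform] → svdfilter → localize → track → render → fsc, driven
by one nested config (YAML sections mirror module names).  A single seed
feeds per-stage substreams derived with ``numpy.random.SeedSequence``, so
toggling one stage does not shift another stage's randomness, and every run
writes a resolved-config snapshot plus a manifest carrying the config hash
and per-stage counts.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beamform as bf
from . import clutterfilt, fsc, localize, render, synth, track
from .core import ImagingGrid, VolumeSequence, wavelength_um, write_volume_sequence

__all__ = ["DEFAULT_CONFIG", "load_config", "resolve_config", "config_hash", "run_pipeline"]

STAGES = ("simulate", "beamform", "svdfilter", "localize", "track", "render", "fsc")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {name: (name != "beamform") for name in STAGES},
    "synth": {
        "n_frames": 500,
        "frame_rate": 500.0,
        "mean_bubbles_in_view": 20.0,
        "radial_mode": "centerline",
        "clutter_amplitude": 31.6,
        "noise_std": 0.05,
    },
    "clutterfilt": {"block_size": 200, "removed_fraction": 0.15},
    "localize": {
        "noise_threshold_frac": 0.03,
        "low_k_std": 1.5,
        "high_k_std": 3.5,
        "connectivity": 26,
        "min_blob_voxels": 2,
    },
    "track": {
        "max_link_distance_mm": 0.2,
        "min_track_length": 10,
        "sg_window": 5,
        "sg_order": 2,
    },
    "render": {"upsample": 10, "sigma": 0.8, "median_kernel": 3},
    "fsc": {"spike_tolerance": 1},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def resolve_config(config: dict | None = None) -> dict:
    return _merge(DEFAULT_CONFIG, config or {})


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    if not isinstance(user, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return resolve_config(user)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


def run_pipeline(config: dict | None = None, outdir: str | Path = "ulm3d_out") -> dict:
    """Execute the enabled stages and return the artifact manifest."""
    config = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seeds = _stage_seeds(int(config["seed"]))
    with open(outdir / "config_resolved.yaml", "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)

    manifest: dict = {"config_hash": chash, "stages": {}, "artifacts": {}}
    stages = config["stages"]

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info

    seq = truth = grid = psf = None

    try:
        if stages.get("simulate"):
            cfg = config["synth"]
            noise = synth.SceneNoiseModel(
                clutter_amplitude=cfg["clutter_amplitude"],
                noise_std=cfg["noise_std"],
                seed=seeds["simulate"],
            )
            _, truth, seq, grid, psf = synth.make_demo_scene(
                seed=seeds["simulate"],
                n_frames=int(cfg["n_frames"]),
                frame_rate=float(cfg["frame_rate"]),
                mean_bubbles_in_view=float(cfg["mean_bubbles_in_view"]),
                radial_mode=cfg["radial_mode"],
                noise=noise,
            )
            scene_path = outdir / "scene.h5"
            write_volume_sequence(seq, scene_path)
            truth.records.to_csv(outdir / "truth.csv", index=False)
            manifest["artifacts"]["scene"] = str(scene_path)
            manifest["artifacts"]["truth"] = str(outdir / "truth.csv")
            record("simulate", n_frames=seq.n_frames,
                   n_truth_records=int(len(truth.records)))

        if stages.get("svdfilter") and seq is not None:
            cfg = clutterfilt.SVDConfig(
                block_size=int(config["clutterfilt"]["block_size"]),
                removed_fraction=float(config["clutterfilt"]["removed_fraction"]),
            )
            seq = clutterfilt.svd_filter_sequence(seq, cfg)
            seq = bf.envelope(seq, method="abs")
            filtered_path = outdir / "filtered.h5"
            write_volume_sequence(seq, filtered_path)
            manifest["artifacts"]["filtered"] = str(filtered_path)
            record("svdfilter", block_size=cfg.block_size,
                   singular_values_removed_per_block=cfg.n_removed(cfg.block_size))

        locs_low = locs_high = None
        if stages.get("localize") and seq is not None:
            cfg = config["localize"]
            base = dict(
                noise_threshold_frac=float(cfg["noise_threshold_frac"]),
                psf=psf or synth.PSFModel.from_frequency(),
                connectivity=int(cfg["connectivity"]),
                min_blob_voxels=int(cfg["min_blob_voxels"]),
            )
            low = localize.LocalizeConfig(segment_k_std=float(cfg["low_k_std"]), **base)
            high = localize.LocalizeConfig(segment_k_std=float(cfg["high_k_std"]), **base)
            locs_low, locs_high = localize.dual_pass_localize(seq, low, high)
            localize.write_localizations(locs_low, outdir / "locs_low.csv")
            localize.write_localizations(locs_high, outdir / "locs_high.csv")
            manifest["artifacts"]["locs_low"] = str(outdir / "locs_low.csv")
            manifest["artifacts"]["locs_high"] = str(outdir / "locs_high.csv")
            record("localize", n_low=len(locs_low), n_high=len(locs_high))

        tracks_low = tracks_high = None
        if stages.get("track") and locs_low is not None:
            cfg = config["track"]
            tcfg = track.TrackConfig(
                max_link_distance_mm=float(cfg["max_link_distance_mm"]),
                min_track_length=int(cfg["min_track_length"]),
                sg_window=int(cfg["sg_window"]),
                sg_order=int(cfg["sg_order"]),
            )
            frame_rate = seq.frame_rate
            tracks_low = track.link_tracks(locs_low, frame_rate, tcfg)
            tracks_high = track.link_tracks(locs_high, frame_rate, tcfg)
            track.write_tracks(tracks_low, outdir / "tracks_low.csv")
            track.write_tracks(tracks_high, outdir / "tracks_high.csv")
            manifest["artifacts"]["tracks_low"] = str(outdir / "tracks_low.csv")
            manifest["artifacts"]["tracks_high"] = str(outdir / "tracks_high.csv")
            record("track", n_tracks_low=len(tracks_low), n_tracks_high=len(tracks_high))

        fused = None
        sr_grid = None
        if stages.get("render") and tracks_low is not None:
            cfg = config["render"]
            up = int(cfg["upsample"])
            sr_grid = ImagingGrid(
                origin_mm=grid.origin_mm,
                spacing_mm=tuple(s / up for s in grid.spacing_mm),
                shape=tuple(n * up for n in grid.shape),
            )
            vol_low = render.accumulate_tracks(tracks_low, sr_grid)
            vol_high = render.accumulate_tracks(tracks_high, sr_grid)
            fused = render.fuse_passes(vol_low.intensity, vol_high.intensity)
            fused = render.final_smooth(fused, float(cfg["sigma"]))
            vz = render.fuse_passes(
                render.velocity_map(vol_low, int(cfg["median_kernel"])),
                render.velocity_map(vol_high, int(cfg["median_kernel"])),
            )
            sr_path = outdir / "superres.h5"
            write_volume_sequence(
                VolumeSequence(np.stack([fused, vz]), sr_grid, seq.frame_rate), sr_path
            )
            manifest["artifacts"]["superres"] = str(sr_path)
            record("render", grid_shape=list(sr_grid.shape),
                   nonzero_voxels=int(np.count_nonzero(fused)))

        if stages.get("fsc") and fused is not None:
            curve = fsc.single_image_fsc(
                fused, sr_grid.spacing_mm,
                spike_tolerance=int(config["fsc"]["spike_tolerance"]),
            )
            pd.DataFrame(
                {
                    "freq_per_um": curve.shell_frequencies_per_um,
                    "fsc": curve.correlation,
                    "n_voxels": curve.n_voxels_per_shell,
                    "threshold": curve.threshold_curve,
                }
            ).to_csv(outdir / "fsc_curve.csv", index=False)
            manifest["artifacts"]["fsc_curve"] = str(outdir / "fsc_curve.csv")
            record("fsc", resolution_um=float(curve.resolution_um))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        done = set(manifest["stages"])
        current = next((s for s in STAGES if stages.get(s) and s not in done), "?")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
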