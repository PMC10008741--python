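"""Sub-voxel localization: thresholding, matched filter, segmentation, centroids."""

import numpy as np
import pytest

from ulm3d import localize as loc
from ulm3d import synth
from ulm3d.core import ImagingGrid, VolumeSequence
from ulm3d.synth import PSFModel, SceneNoiseModel


GRID = ImagingGrid((0.0, -0.8, -0.8), (0.1, 0.1, 0.1), (16, 16, 16))
PSF = PSFModel(0.1, 0.15, 0.15)


class TestNoiseThreshold:
    def test_zero_frac_normalizes_only(self):
        vol = np.array([[[0.005, 0.5, 1.0, 2.0]]])
        out = loc.noise_threshold(vol, 0.0)
        assert out.max() == 1.0
        assert np.all(out > 0)

    def test_values_below_fraction_zeroed(self):
        vol = np.array([[[0.005, 0.5, 1.0]]])
        out = loc.noise_threshold(vol, 0.01)
        assert np.array_equal(out, [[[0.0, 0.5, 1.0]]])

    def test_survivor_count_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        vol = rng.random((8, 8, 8))
        frac = 0.3
        out = loc.noise_threshold(vol, frac)
        oracle = sum(
            1
            for v in vol.ravel()
            if v / vol.max() >= frac
        )
        assert np.count_nonzero(out) == oracle

    def test_all_zero_volume_warns(self):
        with pytest.warns(UserWarning):
            out = loc.noise_threshold(np.zeros((3, 3, 3)), 0.05)
        assert np.all(out == 0)


class TestMatchFilter:
    def test_delta_reproduces_kernel(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        out = loc.match_filter(vol, PSF, GRID.spacing_mm)
        sig = [f / loc.FWHM_TO_SIGMA / s for f, s in zip(PSF.fwhm_mm, GRID.spacing_mm)]
        expected_peak = np.prod(
            [
                1.0 / np.sum(np.exp(-0.5 * (np.arange(-int(np.ceil(3 * s)), int(np.ceil(3 * s)) + 1) / s) ** 2) / np.exp(0))
                * 1.0
                for s in sig
            ]
        )
        # peak equals the product of the normalized 1-D kernel centers
        centers = []
        for s in sig:
            half = max(1, int(np.ceil(3 * s)))
            k = np.exp(-0.5 * (np.arange(-half, half + 1) / s) ** 2)
            centers.append((k / k.sum())[half])
        assert out[7, 7, 7] == pytest.approx(np.prod(centers))

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(1)
        vol = np.zeros((21, 21, 21))
        vol[8:13, 8:13, 8:13] = rng.random((5, 5, 5))
        out = loc.match_filter(vol, PSF, GRID.spacing_mm)
        assert out.sum() == pytest.approx(vol.sum(), rel=1e-6)

    def test_matches_dense_convolution_oracle(self):
        # brute-force sliding-window sum with reflected boundaries on 9³
        rng = np.random.default_rng(2)
        vol = rng.random((9, 9, 9))
        out = loc.match_filter(vol, PSF, GRID.spacing_mm)

        kernels = []
        for axis, f in enumerate(PSF.fwhm_mm):
            s = f / loc.FWHM_TO_SIGMA / GRID.spacing_mm[axis]
            half = max(1, int(np.ceil(3 * s)))
            k = np.exp(-0.5 * (np.arange(-half, half + 1) / s) ** 2)
            kernels.append(k / k.sum())
        kz, kx, ky = kernels
        hz, hx, hy = len(kz) // 2, len(kx) // 2, len(ky) // 2

        def reflect(i, n):
            while not (0 <= i < n):
                i = -i - 1 if i < 0 else 2 * n - 1 - i
            return i

        oracle = np.zeros_like(vol)
        n = 9
        for z in range(n):
            for x in range(n):
                for y in range(n):
                    acc = 0.0
                    for a in range(len(kz)):
                        for b in range(len(kx)):
                            for c in range(len(ky)):
                                zz = reflect(z + a - hz, n)
                                xx = reflect(x + b - hx, n)
                                yy = reflect(y + c - hy, n)
                                acc += kz[a] * kx[b] * ky[c] * vol[zz, xx, yy]
                    oracle[z, x, y] = acc
        assert np.allclose(out, oracle, atol=1e-12)


class TestSegment:
    def test_two_well_separated_gaussians(self):
        zz, xx, yy = np.mgrid[0:24, 0:24, 0:24].astype(float)
        vol = np.exp(-((zz - 6) ** 2 + (xx - 6) ** 2 + (yy - 12) ** 2) / 2.0)
        vol += np.exp(-((zz - 18) ** 2 + (xx - 18) ** 2 + (yy - 12) ** 2) / 2.0)
        _, n = loc.segment(vol, k_std=2.0)
        assert n == 2

    def test_huge_k_removes_everything(self):
        vol = np.random.default_rng(3).random((8, 8, 8))
        _, n = loc.segment(vol, k_std=50.0)
        assert n == 0

    def test_blob_count_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(4)
        vol = (rng.random((10, 10, 10)) > 0.8).astype(float)
        labels, n = loc.segment(vol + 0.0, k_std=0.5, connectivity=6, min_blob_voxels=1)

        # brute-force BFS flood fill with 6-connectivity on the same mask
        mask = vol > vol.mean() + 0.5 * vol.std()
        seen = np.zeros_like(mask, bool)
        count = 0
        for start in np.argwhere(mask):
            if seen[tuple(start)]:
                continue
            count += 1
            stack = [tuple(start)]
            seen[tuple(start)] = True
            while stack:
                z, x, y = stack.pop()
                for dz, dx, dy in [(1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)]:
                    p = (z+dz, x+dx, y+dy)
                    if all(0 <= p[i] < 10 for i in range(3)) and mask[p] and not seen[p]:
                        seen[p] = True
                        stack.append(p)
        assert n == count

    def test_mask_shrinks_monotonically_with_threshold(self):
        # Raising k strictly shrinks the supra-threshold mask (blob *count*
        # can transiently rise when a merged blob splits — that splitting
        # is exactly what the dual-threshold strategy exploits).
        rng = np.random.default_rng(5)
        vol = rng.random((12, 12, 12))
        sizes = []
        for k in (0.5, 1.5, 2.5, 3.5, 50.0):
            labels, _ = loc.segment(vol, k, min_blob_voxels=1)
            sizes.append(np.count_nonzero(labels))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == 0


class TestWeightedCentroid:
    def test_symmetric_weights_give_geometric_center(self):
        idx = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0]])
        pos = loc.weighted_centroid(idx, np.ones(4), GRID)
        assert np.allclose(pos, GRID.index_to_mm(np.array([1.0, 1.0, 0.0])))

    def test_two_voxel_example(self):
        idx = np.array([[0, 0, 0], [1, 0, 0]])
        pos = loc.weighted_centroid(idx, np.array([1.0, 3.0]), GRID)
        assert GRID.mm_to_index(pos)[0] == pytest.approx(0.75)

    def test_matches_definitional_sum(self):
        rng = np.random.default_rng(6)
        idx = rng.integers(0, 16, size=(30, 3))
        w = rng.random(30)
        pos = loc.weighted_centroid(idx, w, GRID)
        oracle_idx = np.zeros(3)
        for i, wi in zip(idx, w):
            oracle_idx += wi * i
        oracle_idx /= w.sum()
        assert np.allclose(pos, GRID.index_to_mm(oracle_idx))

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            loc.weighted_centroid(np.array([[0, 0, 0]]), np.array([0.0]), GRID)


def _bubble_sequence(positions_per_frame, amplitudes=None, n_frames=None):
    """Render noiseless frames with one Gaussian per position."""
    import pandas as pd

    rows = []
    for f, plist in enumerate(positions_per_frame):
        for b, p in enumerate(plist):
            rows.append((b, f, *p, 0.0, 0.0))
    rec = pd.DataFrame(rows, columns=["bubble", "frame", "z_mm", "x_mm", "y_mm", "rho", "speed_mm_s"])
    truth = synth.BubbleTruth(rec, 500.0, len(positions_per_frame))
    amp = amplitudes or (1.0, 1.0)
    return synth.render_bmode(truth, PSF, SceneNoiseModel(0, noise_std=0), GRID,
                              amplitude_range=amp)


class TestLocalizePass:
    config = loc.LocalizeConfig(segment_k_std=1.5, psf=PSF)

    def test_single_bubble_single_localization(self):
        true_pos = (0.74, -0.13, 0.28)
        seq = _bubble_sequence([[true_pos]])
        out = loc.localize_pass(seq, self.config)
        assert len(out) == 1
        err = np.abs(np.array(out[0].position_mm) - true_pos)
        assert np.all(err < 0.05)  # half a voxel

    def test_empty_frames_give_empty_list(self):
        grid = GRID
        seq = VolumeSequence(np.zeros((3,) + grid.shape), grid, 500.0)
        with pytest.warns(UserWarning):
            assert loc.localize_pass(seq, self.config) == []

    def test_two_separated_bubbles_both_recovered(self):
        p1, p2 = (0.4, -0.5, -0.5), (1.2, 0.5, 0.5)
        seq = _bubble_sequence([[p1, p2]])
        out = loc.localize_pass(seq, self.config)
        assert len(out) == 2
        got = sorted([l.position_mm for l in out])
        for g, t in zip(got, sorted([p1, p2])):
            assert np.all(np.abs(np.array(g) - t) < 0.05)

    def test_frame_permutation_permutes_outputs(self):
        seq = _bubble_sequence([[(0.4, -0.4, 0.0)], [(1.0, 0.4, 0.2)]])
        fwd = loc.localize_pass(seq, self.config)
        rev_seq = VolumeSequence(seq.frames[::-1].copy(), seq.grid, seq.frame_rate)
        rev = loc.localize_pass(rev_seq, self.config)
        assert len(fwd) == len(rev) == 2
        assert fwd[0].position_mm == rev[1].position_mm
        assert fwd[1].position_mm == rev[0].position_mm


class TestDualPass:
    def test_identical_configs_identical_sets(self):
        seq = _bubble_sequence([[(0.6, 0.0, 0.0), (1.1, 0.5, -0.3)]])
        cfg = loc.LocalizeConfig(segment_k_std=2.0, psf=PSF)
        a, b = loc.dual_pass_localize(seq, cfg, cfg)
        assert [l.position_mm for l in a] == [l.position_mm for l in b]
        assert {l.pass_label for l in a} == {"low"}
        assert {l.pass_label for l in b} == {"high"}

    def test_low_pass_larger_threshold_rejected(self):
        seq = _bubble_sequence([[(0.6, 0.0, 0.0)]])
        with pytest.raises(ValueError):
            loc.dual_pass_localize(
                seq,
                loc.LocalizeConfig(segment_k_std=3.0, psf=PSF),
                loc.LocalizeConfig(segment_k_std=1.0, psf=PSF),
            )

    def test_bright_pair_merged_by_low_split_by_high(self):
        # one dim bubble far away; two bright bubbles whose Gaussian tails
        # overlap above the low threshold but not above the high one
        dim = (0.4, -0.55, -0.55)
        b1 = (1.1, 0.10, 0.40)
        b2 = (1.1, 0.60, 0.40)
        import pandas as pd

        rows = [(0, 0, *dim, 0.0, 0.0), (1, 0, *b1, 0.0, 0.0), (2, 0, *b2, 0.0, 0.0)]
        rec = pd.DataFrame(rows, columns=["bubble", "frame", "z_mm", "x_mm", "y_mm", "rho", "speed_mm_s"])
        truth = synth.BubbleTruth(rec, 500.0, 1)
        frames = np.zeros((1,) + GRID.shape)
        from ulm3d.synth import _splat_gaussians

        _splat_gaussians(frames[0], GRID, np.array([dim]), np.array([1.0]), PSF.sigma_mm)
        _splat_gaussians(frames[0], GRID, np.array([b1, b2]), np.array([10.0, 10.0]), PSF.sigma_mm)
        seq = VolumeSequence(frames, GRID, 500.0)

        low_cfg = loc.LocalizeConfig(segment_k_std=1.0, psf=PSF)
        high_cfg = loc.LocalizeConfig(segment_k_std=3.5, psf=PSF)
        low, high = loc.dual_pass_localize(seq, low_cfg, high_cfg)

        low_pos = np.array([l.position_mm for l in low])
        high_pos = np.array([l.position_mm for l in high])
        mid = np.mean([b1, b2], axis=0)
        # low pass sees the dim bubble but merges the bright pair
        assert np.min(np.linalg.norm(low_pos - dim, axis=1)) < 0.06
        assert len(low_pos[np.linalg.norm(low_pos - mid, axis=1) < 0.45]) == 1
        # high pass misses the dim bubble but resolves the bright pair
        if len(high_pos):
            assert np.min(np.linalg.norm(high_pos - dim, axis=1)) > 0.06
        assert len(high_pos[np.linalg.norm(high_pos - mid, axis=1) < 0.45]) == 2

    def test_csv_roundtrip(self, tmp_path):
        seq = _bubble_sequence([[(0.6, 0.0, 0.0)]])
        out = loc.localize_pass(seq, loc.LocalizeConfig(segment_k_std=1.5, psf=PSF))
        path = tmp_path / "locs.csv"
        loc.write_localizations(out, path)
        back = loc.read_localizations(path)
        assert len(back) == len(out)
        assert back[0].position_mm == pytest.approx(out[0].position_mm)
        assert back[0].pass_label == out[0].pass_label
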