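"""Phantom geometry, ground-truth microstructure, signal synthesis, splits."""

import numpy as np
import pytest

import cdti
from cdti import phantom
from cdti.maps import fa as fa_of


class TestGeometry:
    def test_boundary_pixel_has_depth_zero(self):
        # spacing 3 mm: a pixel exactly 7 px east of the center sits at 21 mm
        cfg = cdti.PhantomConfig(
            grid_size=(32, 32), pixel_spacing_mm=3.0, center=(16.0, 16.0)
        )
        geom = phantom.make_lv_geometry(cfg)
        assert geom.mask[16, 23]
        assert geom.depth[16, 23] == pytest.approx(0.0, abs=1e-12)

    def test_mid_wall_pixel_is_meso_at_depth_half(self):
        cfg = cdti.PhantomConfig(
            grid_size=(32, 32), pixel_spacing_mm=3.0, center=(16.0, 16.0)
        )
        geom = phantom.make_lv_geometry(cfg)
        # (endo+epi)/2 = 27 mm = 9 px east of center
        assert geom.depth[16, 25] == pytest.approx(0.5, abs=1e-12)
        assert geom.region_labels["meso"][16, 25]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mask_matches_exhaustive_pixel_scan(self, seed):
        rng = np.random.default_rng(seed)
        endo = rng.uniform(15, 25)
        cfg = cdti.PhantomConfig(
            grid_size=(48, 48),
            endo_radius_mm=endo,
            epi_radius_mm=endo + rng.uniform(8, 14),
        )
        geom = phantom.make_lv_geometry(cfg)
        count = 0
        for r in range(48):
            for c in range(48):
                d = np.hypot(r - cfg.center[0], c - cfg.center[1]) * cfg.pixel_spacing_mm
                if cfg.endo_radius_mm <= d <= cfg.epi_radius_mm:
                    count += 1
        assert geom.mask.sum() == count

    def test_degenerate_annulus_raises(self):
        cfg = cdti.PhantomConfig(
            grid_size=(16, 16), endo_radius_mm=1.0, epi_radius_mm=1.2
        )
        with pytest.raises(ValueError, match="degenerate annulus"):
            phantom.make_lv_geometry(cfg)


class TestGroundTruth:
    def test_endocardial_voxel_has_endo_helix_angle(self):
        cfg = cdti.PhantomConfig(
            grid_size=(32, 32), pixel_spacing_mm=3.0, center=(16.0, 16.0)
        )
        truth = phantom.ground_truth_tensors(phantom.make_lv_geometry(cfg), cfg)
        assert truth.ha_truth_deg[16, 23] == pytest.approx(60.0, abs=1e-12)

    def test_md_closed_form_and_meso_conservation(self, noiseless_phantom):
        _, truth, _ = noiseless_phantom
        md = truth.md_truth[truth.mask]
        assert np.allclose(md, (1.8 + 0.8 + 0.6) / 3.0, rtol=1e-12)
        meso = truth.region_labels["meso"]
        endo = truth.region_labels["endo"]
        assert abs(
            np.median(truth.md_truth[meso]) - np.median(truth.md_truth[endo])
        ) < 1e-12
        # the boost itself raises FA by exactly the configured fraction
        fa_meso = truth.fa_truth[meso].mean()
        fa_endo = truth.fa_truth[endo].mean()
        assert fa_meso == pytest.approx(1.15 * fa_endo, rel=1e-9)

    def test_infarct_scales_md_not_fa(self):
        cfg = cdti.PhantomConfig(
            grid_size=(64, 64),
            infarct=phantom.InfarctSpec(0.0, 90.0, md_scale=1.27),
        )
        truth = phantom.ground_truth_tensors(phantom.make_lv_geometry(cfg), cfg)
        endo = truth.region_labels["endo"]
        inf = truth.region_labels["infarct"] & endo
        rem = truth.region_labels["remote"] & endo
        ratio = np.median(truth.md_truth[inf]) / np.median(truth.md_truth[rem])
        assert ratio == pytest.approx(1.27, rel=1e-12)
        assert np.median(truth.fa_truth[inf]) == pytest.approx(
            np.median(truth.fa_truth[rem]), rel=1e-12
        )

    def test_truth_tensors_are_spd_with_correct_fa(self, noiseless_phantom):
        _, truth, _ = noiseless_phantom
        mats = truth.tensor_truth.as_matrices()[truth.mask]
        evals = np.linalg.eigvalsh(mats)
        assert np.all(evals > 0)
        assert np.allclose(
            np.sort(fa_of(evals)), np.sort(truth.fa_truth[truth.mask]), atol=1e-12
        )

    def test_excessive_meso_boost_raises(self):
        with pytest.raises(ValueError):
            cfg = cdti.PhantomConfig(grid_size=(48, 48), meso_fa_boost=2.0)
            phantom.ground_truth_tensors(phantom.make_lv_geometry(cfg), cfg)


class TestSynthesis:
    def test_noiseless_b0_equals_s0(self, noiseless_phantom):
        cfg, truth, ds = noiseless_phantom
        b0 = ds.images[ds.bvals == 0]
        assert np.allclose(b0[:, truth.mask], cfg.s0)
        assert np.all(b0[:, ~truth.mask] == 0)

    def test_isotropic_tensor_gives_direction_independent_signal(self):
        d = 1.0e-3
        cfg = cdti.PhantomConfig(
            grid_size=(48, 48),
            eigenvalues_mm2_per_s=(d, d, d),
            meso_fa_boost=0.0,
            snr=np.inf,
        )
        truth, ds = phantom.simulate(cfg)
        for b in (150.0, 600.0):
            imgs = ds.images[ds.bvals == b]
            assert np.allclose(imgs[:, truth.mask], cfg.s0 * np.exp(-b * d), rtol=1e-12)

    def test_identical_seed_is_bit_identical(self):
        cfg = cdti.PhantomConfig(grid_size=(48, 48), snr=10.0, motion_sigma_px=0.5)
        truth = phantom.ground_truth_tensors(phantom.make_lv_geometry(cfg), cfg)
        a = phantom.synthesize_dwi(truth, seed=99)
        b = phantom.synthesize_dwi(truth, seed=99)
        c = phantom.synthesize_dwi(truth, seed=100)
        assert np.array_equal(a.images, b.images)
        assert not np.array_equal(a.images, c.images)

    def test_rician_bias_at_low_snr(self):
        # magnitude noise biases the mean signal upward at SNR = 2
        cfg = cdti.PhantomConfig(
            grid_size=(128, 128), pixel_spacing_mm=1.0, snr=2.0, seed=3
        )
        truth, ds = phantom.simulate(cfg)
        b0 = ds.images[ds.bvals == 0][:, truth.mask]
        assert b0.size >= 10_000
        assert b0.mean() > cfg.s0

    def test_background_noise_is_rayleigh_not_zero(self):
        cfg = cdti.PhantomConfig(grid_size=(64, 64), snr=10.0, seed=4)
        truth, ds = phantom.simulate(cfg)
        bg = ds.images[0][~truth.mask]
        assert np.all(bg >= 0) and bg.mean() > 0

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="non-unit"):
            phantom.Protocol(directions=np.array([[1.0, 0.0, 0.5]] * 6))


class TestStratifiedSplit:
    def test_largest_remainder_sizes(self):
        parts = phantom.split_stratified(
            list(range(10)), ["a"] * 10, (0.7, 0.15, 0.15), seed=0
        )
        assert [len(p) for p in parts] == [7, 2, 1]
        assert sorted(sum(parts, [])) == list(range(10))

    def test_everything_to_train(self):
        parts = phantom.split_stratified(list(range(5)), ["a"] * 5, (1, 0, 0), seed=0)
        assert sorted(parts[0]) == list(range(5))
        assert parts[1] == [] and parts[2] == []

    def test_two_strata_balanced(self):
        ids = list(range(40))
        strata = ["x"] * 20 + ["y"] * 20
        parts = phantom.split_stratified(ids, strata, (0.5, 0.25, 0.25), seed=1)
        assert [len(p) for p in parts] == [20, 10, 10]
        for p, expected in zip(parts, (10, 5, 5)):
            assert sum(1 for i in p if i < 20) == expected

    def test_parts_disjoint_and_cover(self):
        ids = [f"s{i}" for i in range(23)]
        strata = [i % 3 for i in range(23)]
        parts = phantom.split_stratified(ids, strata, (0.6, 0.2, 0.2), seed=5)
        flat = sum(parts, [])
        assert sorted(flat) == sorted(ids)
        assert len(set(flat)) == len(flat)

    def test_tiny_stratum_goes_to_largest_part(self):
        parts = phantom.split_stratified(
            ["a", "b"], ["s1", "s2"], (0.5, 0.25, 0.25), seed=0
        )
        assert sorted(parts[0]) == ["a", "b"]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            phantom.split_stratified([1, 2], ["a", "a"], (0.5, 0.4), seed=0)
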