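"""Eigensystem, FA/MD, local wall frame, HA/E2A and transmural profiles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cdti import io, maps


def _field_from_matrix(D, hw=(4, 4)):
    comps = np.tile(io.matrices_to_components(D), (*hw, 1))
    return io.TensorField(components=comps, mask=np.ones(hw, bool))


class TestEigensystem:
    def test_diagonal_tensor(self):
        field = _field_from_matrix(np.diag([1.8, 0.8, 0.6]))
        evals, evecs, defined = maps.eigensystem(field)
        assert defined.all()
        assert np.allclose(evals[0, 0], [1.8, 0.8, 0.6])
        assert np.allclose(np.abs(evecs[0, 0]), np.eye(3), atol=1e-12)

    def test_rotated_tensor_rotates_eigenvectors(self):
        R = Rotation.from_euler("zyx", [30, 20, 10], degrees=True).as_matrix()
        lam = np.diag([1.8, 0.8, 0.6])
        field = _field_from_matrix(R @ lam @ R.T)
        evals, evecs, _ = maps.eigensystem(field)
        assert np.allclose(evals[0, 0], [1.8, 0.8, 0.6], atol=1e-12)
        for i in range(3):
            assert abs(np.dot(evecs[0, 0, i], R[:, i])) == pytest.approx(1.0, abs=1e-10)

    def test_sign_disambiguation_with_frame(self):
        frame = maps.local_frame(
            np.ones((4, 4), bool), center=(-5.0, -5.0), pixel_spacing_mm=(1, 1)
        )
        field = _field_from_matrix(np.diag([1.8, 0.8, 0.6]))
        _, evecs, _ = maps.eigensystem(field, frame)
        circ_comp = np.sum(evecs[..., 0, :] * frame.circumferential, axis=-1)
        assert np.all(circ_comp >= 0)
        det = np.linalg.det(np.swapaxes(evecs, -1, -2))
        assert np.all(det > 0)

    def test_nonfinite_voxel_excluded(self):
        comps = np.zeros((3, 3, 6))
        mask = np.ones((3, 3), bool)
        field = io.TensorField(components=comps, mask=mask)
        field.components[1, 1, 0] = np.inf  # poke after validation
        _, _, defined = maps.eigensystem(field)
        assert not defined[1, 1] and defined[0, 0]


class TestFAMD:
    def test_isotropic(self):
        assert maps.fa(np.array([2.0, 2.0, 2.0])) == 0.0
        assert maps.md(np.array([2.0, 2.0, 2.0])) == 2.0

    def test_planar_closed_form(self):
        assert maps.fa(np.array([1.0, 1.0, 0.0])) == pytest.approx(1 / np.sqrt(2))

    def test_md_arithmetic_mean(self):
        assert maps.md(np.array([1.8, 0.8, 0.4])) == pytest.approx(1.0)

    def test_zero_eigenvalues_give_zero_fa(self):
        assert maps.fa(np.zeros(3)) == 0.0


class TestLocalFrame:
    def test_east_voxel_geometry(self):
        mask = np.ones((9, 9), bool)
        mask[4, 4] = False
        frame = maps.local_frame(mask, center=(4.0, 4.0), pixel_spacing_mm=(1, 1))
        # voxel due east: radial = +x, circumferential = +y (CCW), long = +z
        assert np.allclose(frame.radial[4, 8], [1, 0, 0])
        assert np.allclose(frame.circumferential[4, 8], [0, 1, 0])
        assert np.allclose(frame.longitudinal[4, 8], [0, 0, 1])

    def test_orthonormal_triads(self):
        mask = np.ones((9, 9), bool)
        mask[4, 4] = False
        frame = maps.local_frame(mask, center=(4.0, 4.0), pixel_spacing_mm=(2.8, 2.8))
        triads = frame.triads()[mask]
        gram = triads @ np.swapaxes(triads, -1, -2)
        assert np.allclose(gram, np.eye(3), atol=1e-12)

    def test_frame_rotates_with_polar_angle(self):
        mask = np.ones((21, 21), bool)
        mask[10, 10] = False
        frame = maps.local_frame(mask, center=(10.0, 10.0), pixel_spacing_mm=(1, 1))
        c0 = frame.circumferential[10, 15]  # angle 0 (east)
        for r, c in [(5, 10), (10, 5), (3, 17)]:
            dx, dy = c - 10.0, -(r - 10.0)
            theta = np.arctan2(dy, dx)
            Rz = np.array(
                [
                    [np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0],
                    [0, 0, 1],
                ]
            )
            assert np.allclose(frame.circumferential[r, c], Rz @ c0, atol=1e-12)

    def test_center_voxel_in_mask_rejected(self):
        mask = np.ones((5, 5), bool)
        with pytest.raises(ValueError, match="center"):
            maps.local_frame(mask, center=(2.0, 2.0), pixel_spacing_mm=(1, 1))


class TestAngles:
    def _frame(self):
        mask = np.ones((1, 1), bool)
        return maps.CardiacFrame(
            radial=np.array([[[1.0, 0, 0]]]),
            circumferential=np.array([[[0, 1.0, 0]]]),
            longitudinal=np.array([[[0, 0, 1.0]]]),
            center=(0.0, -5.0),
        )

    def test_circumferential_e1_gives_zero_ha(self):
        frame = self._frame()
        ha, ok = maps.helix_angle(frame.circumferential, frame)
        assert ok.all() and ha[0, 0] == pytest.approx(0.0)

    def test_longitudinal_e1_gives_ninety(self):
        frame = self._frame()
        ha, ok = maps.helix_angle(frame.longitudinal, frame)
        assert abs(ha[0, 0]) == pytest.approx(90.0)

    def test_radial_e1_flagged_undefined(self):
        frame = self._frame()
        ha, ok = maps.helix_angle(frame.radial, frame)
        assert not ok.any() and np.isnan(ha[0, 0])

    def test_e2_on_tangential_reference_gives_zero(self):
        frame = self._frame()
        e1 = frame.circumferential
        t = np.cross(e1, frame.radial)
        e2a, abs_e2a, ok = maps.sheetlet_angle(e1, t, frame)
        assert ok.all() and e2a[0, 0] == pytest.approx(0.0)

    def test_e2_radial_gives_ninety(self):
        frame = self._frame()
        e1 = frame.circumferential
        e2a, abs_e2a, ok = maps.sheetlet_angle(e1, frame.radial, frame)
        assert abs_e2a[0, 0] == pytest.approx(90.0)

    def test_e2a_undefined_when_e1_radial(self):
        frame = self._frame()
        _, _, ok = maps.sheetlet_angle(frame.radial, frame.circumferential, frame)
        assert not ok.any()

    def test_fold_angle_range(self):
        rng = np.random.default_rng(0)
        vals = maps.fold_angle(rng.uniform(-720, 720, 1000))
        assert np.all(vals >= -90) and np.all(vals < 90)
        assert maps.fold_angle(120.0) == pytest.approx(-60.0)


class TestNoiselessRoundTrip:
    def test_maps_recover_truth(self, noiseless_fit, noiseless_phantom):
        cfg, truth, _ = noiseless_phantom
        _, _, res = noiseless_fit
        pm = maps.parameter_maps(res.tensor, center=cfg.center)
        m = truth.mask
        assert np.nanmax(np.abs(pm.fa[m] - truth.fa_truth[m])) < 1e-6
        assert np.nanmax(np.abs(pm.md[m] - truth.md_truth[m])) < 1e-6
        assert np.nanmax(np.abs(pm.ha[m] - truth.ha_truth_deg[m])) < 1e-6
        assert np.nanmax(np.abs(pm.abs_e2a[m] - np.abs(truth.e2a_truth_deg[m]))) < 1e-6

    def test_angle_ranges(self, noisy_phantom):
        import cdti

        cfg, truth, ds = noisy_phantom
        pm = maps.parameter_maps(cdti.lls_fit(ds).tensor, center=cfg.center)
        ha = pm.ha[pm.ha_defined]
        e2a = pm.e2a[pm.e2a_defined]
        assert np.all((ha >= -90) & (ha <= 90))
        assert np.all((e2a >= -90) & (e2a <= 90))
        assert np.all(pm.abs_e2a[pm.e2a_defined] <= 90)


class TestHAProfiles:
    def _ramp(self, hw=64, r0_mm=20.0, wall_mm=12.0, spacing=1.0):
        center = ((hw - 1) / 2.0, (hw - 1) / 2.0)
        rows, cols = np.mgrid[0:hw, 0:hw].astype(float)
        r = np.hypot(rows - center[0], cols - center[1]) * spacing
        mask = (r >= r0_mm) & (r <= r0_mm + wall_mm)
        ha = np.where(mask, 60.0 - 120.0 * (r - r0_mm) / wall_mm, np.nan)
        return ha, mask, center, spacing

    def test_linear_ramp_gradient(self):
        ha, mask, center, sp = self._ramp()
        prof = maps.ha_profiles(ha, mask, center, (sp, sp))
        # 120 degrees over a 12 mm wall -> 10 deg/mm
        assert prof.mean_gradient_deg_per_mm == pytest.approx(10.0, rel=0.05)
        assert np.all(prof.slopes_deg_per_mm < 0)  # decreasing endo -> epi

    def test_ramp_endo_epi_range(self):
        ha, mask, center, sp = self._ramp()
        prof = maps.ha_profiles(ha, mask, center, (sp, sp))
        # discrete sampling cannot exceed (and should approach) the full ramp
        assert 100.0 <= prof.median_range_deg <= 120.0

    def test_constant_map_gives_zero_statistics(self):
        _, mask, center, sp = self._ramp()
        const = np.where(mask, 42.0, np.nan)
        prof = maps.ha_profiles(const, mask, center, (sp, sp))
        assert prof.mean_gradient_deg_per_mm == pytest.approx(0.0, abs=1e-9)
        assert prof.median_iqr_deg == 0.0
        assert prof.median_range_deg == 0.0

    def test_profile_distances_strictly_increasing(self):
        ha, mask, center, sp = self._ramp()
        prof = maps.ha_profiles(ha, mask, center, (sp, sp))
        assert prof.n_profiles > 0
        for dist_mm, depth, _ in prof.profiles:
            assert np.all(np.diff(dist_mm) > 0)
            assert depth[0] == 0.0 and depth[-1] == 1.0


class TestRegionalStats:
    def test_meso_fa_band_detected(self, noiseless_fit, noiseless_phantom):
        cfg, truth, _ = noiseless_phantom
        _, _, res = noiseless_fit
        pm = maps.parameter_maps(res.tensor, center=cfg.center)
        stats = maps.regional_stats(
            pm.fa, {k: truth.region_labels[k] for k in ("endo", "meso", "epi")}
        )
        assert stats.loc["meso", "median"] > stats.loc["endo", "median"]
        assert stats.loc["meso", "median"] > stats.loc["epi", "median"]

    def test_constant_map_zero_std(self):
        mask = np.ones((5, 5), bool)
        stats = maps.regional_stats(np.full((5, 5), 3.0), {"all": mask})
        assert stats.loc["all", "std"] == 0.0
        assert maps.myocardial_std(np.full((5, 5), 3.0), mask) == 0.0

    def test_empty_region_flagged(self):
        stats = maps.regional_stats(np.ones((3, 3)), {"none": np.zeros((3, 3), bool)})
        assert bool(stats.loc["none", "empty"])
        assert np.isnan(stats.loc["none", "median"])
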