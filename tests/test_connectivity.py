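"""Sphere geometry, one-model cleaning, and Fisher-z connectivity."""

import numpy as np
import pytest

import fcresponse as fr
from fcresponse.connectivity import GridSpec
from fcresponse.exceptions import DegenerateDataError
from fcresponse.synthetic import centered_affine

from conftest import data_with_exact_corr


@pytest.fixture
def grid21():
    return GridSpec((21, 21, 21), centered_affine((21, 21, 21)))


class TestSphereRois:
    def test_grid_aligned_sphere_has_81_voxels(self, grid21):
        rois = fr.build_sphere_rois(np.array([[0.0, 0.0, 0.0]]), grid21)
        assert len(rois.voxel_indices[0]) == 81

    def test_mask_can_reduce_roi_to_one_voxel(self, grid21):
        mask = np.zeros((21, 21, 21), dtype=bool)
        mask[10, 10, 10] = True  # grid center
        rois = fr.build_sphere_rois(
            np.array([[0.0, 0.0, 0.0]]), grid21, subject_masks=[mask]
        )
        assert len(rois.voxel_indices[0]) == 1

    def test_empty_roi_after_masking_rejected(self, grid21):
        mask = np.zeros((21, 21, 21), dtype=bool)
        with pytest.raises(ValueError, match="no voxels"):
            fr.build_sphere_rois(
                np.array([[0.0, 0.0, 0.0]]), grid21, subject_masks=[mask]
            )

    def test_overlap_split_by_nearness_geometric_oracle(self, grid21):
        centers = np.array([[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]])
        rois = fr.build_sphere_rois(centers, grid21)
        sets = [set(map(tuple, v)) for v in rois.voxel_indices]
        assert not sets[0] & sets[1]
        # oracle: enumerate every voxel within 5 mm of either center and
        # assign to the nearer one (tie -> lower id)
        expected = [set(), set()]
        for i in range(21):
            for j in range(21):
                for k in range(21):
                    mm = grid21.voxel_centers_mm(np.array([i, j, k]))[0]
                    d = np.linalg.norm(mm - centers, axis=1)
                    inside = d <= 5.0
                    if inside.any():
                        cand = np.nonzero(inside)[0]
                        expected[cand[np.argmin(d[cand])]].add((i, j, k))
        assert sets[0] == expected[0]
        assert sets[1] == expected[1]

    def test_center_outside_grid_listed(self, grid21):
        with pytest.raises(ValueError, match="node 0"):
            fr.build_sphere_rois(np.array([[100.0, 0.0, 0.0]]), grid21)


class TestExtraction:
    def test_constant_volume(self, grid21):
        rois = fr.build_sphere_rois(np.array([[0.0, 0.0, 0.0]]), grid21)
        vol = np.full((21, 21, 21, 7), 3.25)
        ts = fr.extract_timeseries(vol, rois)
        np.testing.assert_array_equal(ts, np.full((1, 7), 3.25))

    def test_single_voxel_roi_exact(self, grid21, rng):
        mask = np.zeros((21, 21, 21), dtype=bool)
        mask[10, 10, 10] = True
        rois = fr.build_sphere_rois(
            np.array([[0.0, 0.0, 0.0]]), grid21, subject_masks=[mask]
        )
        vol = rng.standard_normal((21, 21, 21, 9))
        ts = fr.extract_timeseries(vol, rois)
        np.testing.assert_array_equal(ts[0], vol[10, 10, 10])

    def test_grid_mismatch_rejected(self, grid21):
        rois = fr.build_sphere_rois(np.array([[0.0, 0.0, 0.0]]), grid21)
        with pytest.raises(ValueError):
            fr.extract_timeseries(np.zeros((5, 5, 5, 3)), rois)


class TestTissuePCs:
    def test_rank_one_recovers_shared_signal(self, rng):
        sig = rng.standard_normal(60)
        load = rng.uniform(0.5, 2.0, size=12)
        x = np.outer(load, sig)
        pcs, flags = fr.tissue_pcs(x, k=3)
        zsig = (sig - sig.mean()) / sig.std(ddof=1)
        r = np.corrcoef(pcs[:, 0], zsig)[0, 1]
        assert abs(r) > 1 - 1e-10
        assert flags.get("degenerate") == [1, 2]

    def test_orthogonal_signals_ordered_by_variance(self, rng):
        n = 120
        s1 = np.cos(2 * np.pi * np.arange(n) / 16) * 3.0
        s2 = np.sin(2 * np.pi * np.arange(n) / 8) * 1.0
        x = np.vstack([
            1.0 * s1 + 0.2 * s2,
            0.8 * s1 - 0.3 * s2,
            -0.9 * s1 + 0.25 * s2,
            0.7 * s1 + 0.35 * s2,
            0.85 * s1 - 0.15 * s2,
        ])
        pcs, _ = fr.tissue_pcs(x, k=2)
        assert abs(np.corrcoef(pcs[:, 0], s1)[0, 1]) > 0.99
        assert abs(np.corrcoef(pcs[:, 1], s2)[0, 1]) > 0.99

    def test_k_zero_empty(self):
        pcs, _ = fr.tissue_pcs(np.ones((4, 10)), k=0)
        assert pcs.shape == (10, 0)

    def test_fewer_voxels_than_k_flagged(self, rng):
        pcs, flags = fr.tissue_pcs(rng.standard_normal((3, 50)), k=5)
        assert pcs.shape[1] == 3
        assert flags["available"] == 3


class TestSimultaneousClean:
    tr, n = 2.5, 400  # 1000 s run: 0.001 Hz sits on the frequency grid

    def spec(self, censor=None):
        return fr.CleanSpec(tr=self.tr, passband=(0.01, 0.10), censor=censor)

    def t(self):
        return np.arange(self.n) * self.tr

    @staticmethod
    def amp(x):
        return np.sqrt(2 * np.mean(np.asarray(x) ** 2))

    def test_stopband_attenuation_40db(self):
        t = self.t()
        drift = np.sin(2 * np.pi * 0.001 * t)
        nyq = np.cos(2 * np.pi * 0.2 * t)
        out = fr.simultaneous_clean(np.vstack([drift, nyq]), None, self.spec())
        for row, inp in zip(out, (drift, nyq)):
            ratio = self.amp(row) / self.amp(inp)
            assert 20 * np.log10(ratio + 1e-300) < -40

    def test_passband_preserved_within_1pct(self):
        t = self.t()
        mid = np.sin(2 * np.pi * 0.05 * t)
        out = fr.simultaneous_clean(mid[None, :], None, self.spec())
        assert abs(self.amp(out[0]) / self.amp(mid) - 1) < 0.01

    def test_nuisance_equal_to_node_series_zeroed(self, rng):
        y = fr.bandpass_fft(rng.standard_normal((1, self.n)), self.spec())
        out = fr.simultaneous_clean(y, y[0][:, None], self.spec())
        assert np.abs(out).max() < 1e-8 * np.abs(y).max()

    def test_idempotent(self, rng):
        y = rng.standard_normal((3, self.n))
        once = fr.simultaneous_clean(y, None, self.spec())
        twice = fr.simultaneous_clean(once, None, self.spec())
        np.testing.assert_allclose(twice, once, atol=1e-8)

    def test_fft_path_agrees(self, rng):
        y = rng.standard_normal((4, self.n))
        a = fr.simultaneous_clean(y, None, self.spec())
        b = fr.bandpass_fft(y, self.spec())
        assert np.abs(a - b).max() < 1e-6

    def test_censored_frames_dropped_and_residual_orthogonal(self, rng):
        y = rng.standard_normal((3, self.n))
        nuis = rng.standard_normal((self.n, 2))
        censor = np.zeros(self.n, dtype=bool)
        censor[rng.choice(self.n, 40, replace=False)] = True
        spec = self.spec(censor=censor)
        out = fr.simultaneous_clean(y, nuis, spec)
        assert out.shape == (3, self.n - 40)
        # residuals orthogonal to the band-limited nuisance on retained frames
        from fcresponse.connectivity import _project_onto, _spectral_basis
        retained = np.nonzero(~censor)[0]
        _, pas = _spectral_basis(self.n, self.tr, retained, (0.01, 0.10))
        nf = _project_onto(nuis[retained], pas)
        dots = np.abs(out @ nf) / (np.linalg.norm(out) * np.linalg.norm(nf))
        assert dots.max() < 1e-8

    def test_empty_passband_after_discretization_rejected(self):
        # 10 frames at tr 2.5 s -> frequency grid spacing 0.04 Hz; a band of
        # (0.011, 0.019) contains no representable frequency
        spec = fr.CleanSpec(tr=self.tr, passband=(0.011, 0.019))
        with pytest.raises(DegenerateDataError, match="passband"):
            fr.simultaneous_clean(np.ones((1, 10)), None, spec)

    def test_inverted_passband_rejected(self):
        with pytest.raises(ValueError):
            fr.CleanSpec(tr=self.tr, passband=(0.10, 0.01))


class TestConnectivityMatrix:
    def test_perfectly_correlated_nodes_rejected(self):
        x = np.linspace(0, 1, 50)
        with pytest.raises(DegenerateDataError, match="degenerate"):
            fr.connectivity_matrix(np.vstack([x, 2 * x + 1]))

    def test_zero_variance_node_named(self):
        y = np.vstack([np.ones(30), np.random.default_rng(0).standard_normal(30)])
        with pytest.raises(DegenerateDataError, match="0"):
            fr.connectivity_matrix(y)

    def test_white_noise_z_small(self, rng):
        y = rng.standard_normal((6, 2000))
        z = fr.connectivity_matrix(y).z
        off = ~np.eye(6, dtype=bool)
        assert np.abs(z[off]).mean() < 0.05

    def test_known_r_gives_closed_form_z(self, rng):
        R = np.array([[1.0, 0.9], [0.9, 1.0]])
        y = data_with_exact_corr(R, 100, rng).T
        z = fr.connectivity_matrix(y).z
        assert z[0, 1] == pytest.approx(np.arctanh(0.9), abs=1e-10)
        assert z[0, 1] == pytest.approx(1.4722, abs=1e-4)

    def test_affine_rescaling_invariance(self, rng):
        y = rng.standard_normal((5, 80))
        z1 = fr.connectivity_matrix(y).z
        scale = rng.uniform(0.5, 3.0, size=(5, 1))
        shift = rng.uniform(-2, 2, size=(5, 1))
        z2 = fr.connectivity_matrix(y * scale + shift).z
        np.testing.assert_allclose(z1, z2, atol=1e-10)


class TestMeanAndDifference:
    def test_zero_matrices(self):
        z = np.zeros((4, 4))
        assert fr.mean_connectivity(z, z) == 0.0

    def test_constant_triangles(self):
        n = 5
        zv = np.full((n, n), 0.4)
        zp = np.full((n, n), 0.2)
        np.fill_diagonal(zv, 0)
        np.fill_diagonal(zp, 0)
        assert fr.mean_connectivity(zv, zp) == pytest.approx(0.3, abs=1e-12)

    def test_mean_matches_loop_oracle(self, rng):
        n = 7
        zv = fr.vec_to_matrix(rng.standard_normal(fr.n_edges(n)), n)
        zp = fr.vec_to_matrix(rng.standard_normal(fr.n_edges(n)), n)
        vals = []
        for i in range(n):
            for j in range(i + 1, n):
                vals += [zv[i, j], zp[i, j]]
        assert fr.mean_connectivity(zv, zp) == pytest.approx(
            np.mean(vals), abs=1e-12
        )

    def test_difference_elementwise_oracle(self, rng):
        n = 6
        zv = fr.vec_to_matrix(rng.standard_normal(fr.n_edges(n)), n)
        zp = fr.vec_to_matrix(rng.standard_normal(fr.n_edges(n)), n)
        d = fr.difference_matrix(zv, zp)
        for i in range(n):
            for j in range(n):
                expected = 0.0 if i == j else zv[i, j] - zp[i, j]
                assert d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_identical_conditions_zero(self, rng):
        z = fr.vec_to_matrix(rng.standard_normal(fr.n_edges(4)), 4)
        np.testing.assert_array_equal(fr.difference_matrix(z, z), np.zeros((4, 4)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fr.difference_matrix(np.zeros((3, 3)), np.zeros((4, 4)))


class TestEndToEnd:
    def test_planted_inter_roi_correlation_recovered(self):
        # two ROIs with population r = 0.5 over 240 frames; the estimate
        # should land within +/-0.12 in nearly every realization
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 240
            base = rng.standard_normal(n)
            s1 = base
            s2 = 0.5 * base + np.sqrt(0.75) * rng.standard_normal(n)
            fx = fr.gen_nifti_fixture(
                n, (16, 16, 16), 2.44,
                np.array([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]]),
                roi_signals=np.vstack([s1, s2]), noise_sd=0.0, seed=seed,
            )
            rois = fr.build_sphere_rois(
                np.array([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]]),
                GridSpec((16, 16, 16), fx.img.affine),
            )
            ts = fr.extract_timeseries(fx.data, rois)
            r = np.corrcoef(ts)[0, 1]
            if abs(r - 0.5) <= 0.12:
                hits += 1
        assert hits >= 7
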