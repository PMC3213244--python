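import numpy as np
import pytest

from enmkit import coarse_grain as cg
from enmkit import enm_build as eb
from enmkit import fixtures as fx
from enmkit import mode_analysis as ma

from conftest import point_model


def gnm_modes(coords, cutoff, gamma=1.0):
    pts = point_model(coords)
    cm = eb.contact_map_cutoff(pts, cutoff, gamma)
    return ma.solve_modes(eb.assemble_gnm(cm, pts.coords))


def anm_modes(coords, cutoff, gamma=1.0):
    pts = point_model(coords)
    cm = eb.contact_map_cutoff(pts, cutoff, gamma)
    return ma.solve_modes(eb.assemble_anm(cm, pts.coords))


@pytest.fixture
def two_node_gnm():
    return gnm_modes([[0, 0, 0], [5, 0, 0]], 7.3)


class TestSolveModes:
    def test_path3_eigenvalues(self, path3_gnm_modes):
        # characteristic polynomial of [[1,-1,0],[-1,2,-1],[0,-1,1]] -> {0,1,3}
        np.testing.assert_allclose(path3_gnm_modes.eigenvalues, [0, 1, 3], atol=1e-10)

    def test_anm_lattice_six_zero_modes(self, lattice27_anm_modes):
        assert lattice27_anm_modes.n_zero == 6

    def test_gnm_single_zero_mode_all_ones(self, path3_gnm_modes):
        assert path3_gnm_modes.n_zero == 1
        v0 = path3_gnm_modes.eigenvectors[:, 0]
        np.testing.assert_allclose(v0, v0[0], atol=1e-10)
        assert v0[0] != 0

    def test_orthonormal_columns(self, lattice27_anm_modes):
        q = lattice27_anm_modes.eigenvectors
        np.testing.assert_allclose(q.T @ q, np.eye(q.shape[1]), atol=1e-8)

    def test_full_spectrum_reconstruction(self, lattice27):
        d = eb.ENMDefinition(kind="anm", scheme="cutoff", cutoff=2.0)
        sm = eb.build_stiffness(lattice27, d)
        ms = ma.solve_modes(sm)
        recon = ms.eigenvectors @ np.diag(ms.eigenvalues) @ ms.eigenvectors.T
        dense = sm.dense()
        rel = np.linalg.norm(recon - dense) / np.linalg.norm(dense)
        assert rel < 1e-6

    def test_sparse_dense_agreement(self, lattice27):
        d = eb.ENMDefinition(kind="anm", scheme="cutoff", cutoff=2.0)
        sm = eb.build_stiffness(lattice27, d)
        dense = ma.solve_modes(sm, method="dense")
        k = 26
        sparse = ma.solve_modes(sm, n_modes=k, method="sparse_lowest")
        assert sparse.partial
        rel = np.abs(sparse.eigenvalues - dense.eigenvalues[:k])
        scale = np.maximum(np.abs(dense.eigenvalues[:k]), 1e-12)
        nz = dense.eigenvalues[:k] > 1e-8 * dense.eigenvalues.max()
        assert np.all(rel[nz] / scale[nz] < 1e-8)
        # eigenvectors agree up to sign on non-degenerate modes
        assert sparse.n_zero == 6

    def test_invalid_method(self, path3_gnm_modes, lattice27):
        d = eb.ENMDefinition(kind="gnm", scheme="cutoff", cutoff=1.05)
        sm = eb.build_stiffness(lattice27, d)
        with pytest.raises(ValueError):
            ma.solve_modes(sm, method="magic")
        with pytest.raises(ValueError):
            ma.solve_modes(sm, n_modes="all", method="sparse_lowest")


class TestPseudoInverse:
    def test_two_node_value(self, two_node_gnm):
        cov = ma.pseudo_inverse(two_node_gnm)
        np.testing.assert_allclose(cov, [[0.25, -0.25], [-0.25, 0.25]], atol=1e-12)

    def test_path3_diagonal(self, path3_gnm_modes):
        cov = ma.pseudo_inverse(path3_gnm_modes)
        np.testing.assert_allclose(np.diag(cov), [5 / 9, 2 / 9, 5 / 9], atol=1e-10)

    def test_matches_numpy_pinv_oracle(self, lattice27):
        d = eb.ENMDefinition(kind="gnm", scheme="cutoff", cutoff=1.8)
        sm = eb.build_stiffness(lattice27, d)
        cov = ma.pseudo_inverse(ma.solve_modes(sm))
        # explicit rcond so the oracle cuts the same near-zero mode
        np.testing.assert_allclose(cov, np.linalg.pinv(sm.dense(), rcond=1e-10),
                                   atol=1e-8)

    def test_penrose_identity(self, lattice27_anm_modes, lattice27):
        d = eb.ENMDefinition(kind="anm", scheme="cutoff", cutoff=2.0)
        h = eb.build_stiffness(lattice27, d).dense()
        cov = ma.pseudo_inverse(lattice27_anm_modes)
        np.testing.assert_allclose(h @ cov @ h, h, atol=1e-6)

    def test_partial_equals_truncated(self, lattice27):
        d = eb.ENMDefinition(kind="gnm", scheme="cutoff", cutoff=1.05)
        sm = eb.build_stiffness(lattice27, d)
        full = ma.solve_modes(sm)
        # k = 7 ends exactly at a degeneracy boundary (spectrum 0,1,1,1,2,2,2);
        # splitting a degenerate block would make the comparison basis-dependent
        k = 7
        partial = ma.solve_modes(sm, n_modes=k, method="sparse_lowest")
        q = full.eigenvectors[:, full.n_zero:k]
        lam = full.eigenvalues[full.n_zero:k]
        truncated = (q / lam) @ q.T
        np.testing.assert_allclose(ma.pseudo_inverse(partial), truncated, atol=1e-8)

    def test_all_zero_modes_error(self):
        ms = ma.ModeSet(kind="gnm", eigenvalues=np.zeros(2),
                        eigenvectors=np.eye(2), n_zero=2, n_nodes=2,
                        coords=np.zeros((2, 3)))
        with pytest.raises(ValueError):
            ma.pseudo_inverse(ms)


class TestFluctuations:
    def test_two_node_msf(self, two_node_gnm):
        np.testing.assert_allclose(ma.mean_square_fluctuations(two_node_gnm).msf,
                                   [0.25, 0.25], atol=1e-12)

    def test_path3_msf(self, path3_gnm_modes):
        msf = ma.mean_square_fluctuations(path3_gnm_modes).msf
        np.testing.assert_allclose(msf, [0.5556, 0.2222, 0.5556], atol=1e-4)

    def test_msf_palindromic_for_symmetric_path(self):
        msf = gnm_modes([[i * 3.0, 0, 0] for i in range(7)], 3.5).eigenvalues
        fr = ma.mean_square_fluctuations(
            gnm_modes([[i * 3.0, 0, 0] for i in range(7)], 3.5))
        np.testing.assert_allclose(fr.msf, fr.msf[::-1], atol=1e-10)

    def test_anm_msf_rotation_invariant(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 4, size=(6, 3))
        m1 = ma.mean_square_fluctuations(anm_modes(coords, 4.0)).msf
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        m2 = ma.mean_square_fluctuations(anm_modes(coords @ q.T, 4.0)).msf
        np.testing.assert_allclose(m1, m2, atol=1e-8)

    def test_msf_nonnegative(self, lattice27_anm_modes):
        assert np.all(ma.mean_square_fluctuations(lattice27_anm_modes).msf >= 0)


class TestInternalDistanceFluctuations:
    def test_two_node_pair(self, two_node_gnm):
        np.testing.assert_allclose(
            ma.internal_distance_fluctuations(two_node_gnm, [(0, 1)]), [1.0],
            atol=1e-12)

    def test_path3_end_pair(self, path3_gnm_modes):
        np.testing.assert_allclose(
            ma.internal_distance_fluctuations(path3_gnm_modes, [(0, 2)]), [2.0],
            atol=1e-10)

    def test_same_index_rejected(self, path3_gnm_modes):
        with pytest.raises(ValueError):
            ma.internal_distance_fluctuations(path3_gnm_modes, [(1, 1)])

    def test_nonnegative_on_random_fixtures(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            coords = rng.uniform(0, 5, size=(8, 3))
            modes = gnm_modes(coords, 6.0)
            if modes.n_zero != 1:
                continue  # disconnected draw
            pairs = [(i, j) for i in range(8) for j in range(i + 1, 8)]
            vals = ma.internal_distance_fluctuations(modes, pairs)
            assert np.all(vals >= -1e-10)

    def test_anm_pair_nonnegative(self, lattice27_anm_modes):
        vals = ma.internal_distance_fluctuations(
            lattice27_anm_modes, [(0, 26), (0, 1), (13, 22)])
        assert np.all(vals >= -1e-10)


class TestCrossCorrelations:
    def test_unit_diagonal(self, path3_gnm_modes):
        c = ma.cross_correlations(path3_gnm_modes)
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)

    def test_two_node_anticorrelated(self, two_node_gnm):
        c = ma.cross_correlations(two_node_gnm)
        assert c[0, 1] == pytest.approx(-1.0)

    def test_symmetric_and_bounded(self, lattice27_anm_modes):
        c = ma.cross_correlations(lattice27_anm_modes)
        np.testing.assert_allclose(c, c.T, atol=1e-10)
        assert c.min() >= -1.0 and c.max() <= 1.0


class TestAdpTensors:
    def test_gnm_rejected(self, path3_gnm_modes):
        with pytest.raises(ValueError, match="anisotropic"):
            ma.adp_tensors(path3_gnm_modes)

    def test_isotropic_node_identity_tensor(self):
        # center node pinned by symmetric neighbors on all axes
        coords = [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                  [0, 0, 1], [0, 0, -1]]
        modes = anm_modes(coords, 1.5)
        tensors = ma.adp_tensors(modes)
        t0 = tensors[0]
        assert np.allclose(t0, t0[0, 0] * np.eye(3), atol=1e-8)
        sim, _ = ma.compare_adp(tensors[:1], np.eye(3)[None, :, :])
        assert sim[0] == pytest.approx(1.0)

    def test_self_comparison(self, lattice27_anm_modes):
        tensors = ma.adp_tensors(lattice27_anm_modes)
        sim, r = ma.compare_adp(tensors, tensors)
        np.testing.assert_allclose(sim, 1.0, atol=1e-10)
        assert r == pytest.approx(1.0)

    def test_two_node_against_brute_force(self):
        coords = [[0, 0, 0], [2, 0, 0]]
        modes = anm_modes(coords, 3.0)
        tensors = ma.adp_tensors(modes)
        pts = point_model(coords)
        cm = eb.contact_map_cutoff(pts, 3.0)
        h = eb.assemble_anm(cm, pts.coords).dense()
        pinv = np.linalg.pinv(h)
        for i in range(2):
            np.testing.assert_allclose(
                tensors[i], pinv[3 * i:3 * i + 3, 3 * i:3 * i + 3], atol=1e-10)


class TestCollectivity:
    def test_uniform_mode_is_one(self):
        ms = ma.ModeSet(kind="gnm",
                        eigenvalues=np.array([0.0, 1.0]),
                        eigenvectors=np.column_stack([
                            np.ones(4) / 2.0,
                            np.array([1, -1, 1, -1]) / 2.0]),
                        n_zero=1, n_nodes=4, coords=np.zeros((4, 3)))
        assert ma.collectivity(ms, 1) == pytest.approx(1.0)

    def test_localized_mode_is_one_over_n(self):
        v = np.zeros(5)
        v[2] = 1.0
        ms = ma.ModeSet(kind="gnm", eigenvalues=np.array([0.0, 1.0]),
                        eigenvectors=np.column_stack([np.ones(5) / np.sqrt(5), v]),
                        n_zero=1, n_nodes=5, coords=np.zeros((5, 3)))
        assert ma.collectivity(ms, 1) == pytest.approx(1 / 5)

    def test_random_vector_matches_brute_force(self):
        rng = np.random.default_rng(13)
        v = rng.normal(size=10)
        v /= np.linalg.norm(v)
        ms = ma.ModeSet(kind="gnm", eigenvalues=np.array([0.0, 1.0]),
                        eigenvectors=np.column_stack([np.ones(10) / np.sqrt(10), v]),
                        n_zero=1, n_nodes=10, coords=np.zeros((10, 3)))
        u2 = v ** 2 / np.sum(v ** 2)
        expected = np.exp(-np.sum(u2 * np.log(u2))) / 10
        assert ma.collectivity(ms, 1) == pytest.approx(expected)

    def test_zero_mode_rejected(self, path3_gnm_modes):
        with pytest.raises(ValueError, match="zero"):
            ma.collectivity(path3_gnm_modes, 0)


class TestSubsetDirectionalCorrelation:
    def _toy_modes(self, disp):
        n = len(disp)
        v = np.asarray(disp, float).ravel()
        v = v / np.linalg.norm(v)
        vecs = np.zeros((3 * n, 2))
        vecs[:, 1] = v
        vecs[0, 0] = 1.0
        return ma.ModeSet(kind="anm", eigenvalues=np.array([0.0, 1.0]),
                          eigenvectors=vecs, n_zero=1, n_nodes=n,
                          coords=np.arange(3 * n, dtype=float).reshape(n, 3))

    def test_single_subset(self):
        ms = self._toy_modes([[1, 0, 0], [1, 0, 0]])
        out = ma.subset_directional_correlation(ms, 1, [[0, 1]])
        np.testing.assert_allclose(out, [[1.0]])

    def test_antiparallel_hinge(self):
        ms = self._toy_modes([[1, 0, 0], [-1, 0, 0]])
        out = ma.subset_directional_correlation(ms, 1, [[0], [1]])
        assert out[0, 1] == pytest.approx(-1.0)
        assert out[1, 0] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal(self, lattice27_anm_modes):
        out = ma.subset_directional_correlation(
            lattice27_anm_modes, 6, [[0, 1, 2], [10, 11], [20, 25, 26]])
        np.testing.assert_allclose(out, out.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(out), 1.0)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_overlapping_subsets_rejected(self, lattice27_anm_modes):
        with pytest.raises(ValueError, match="disjoint"):
            ma.subset_directional_correlation(lattice27_anm_modes, 6, [[0, 1], [1, 2]])

    def test_gnm_rejected(self, path3_gnm_modes):
        with pytest.raises(ValueError):
            ma.subset_directional_correlation(path3_gnm_modes, 1, [[0], [1]])


class TestBfactorComparison:
    def test_exact_linearity(self, lattice27_anm_modes):
        fr = ma.mean_square_fluctuations(lattice27_anm_modes)
        out = ma.bfactor_comparison(fr, 2.0 * fr.msf)
        assert out.pearson_r == pytest.approx(1.0)

    def test_anti_linearity(self, lattice27_anm_modes):
        fr = ma.mean_square_fluctuations(lattice27_anm_modes)
        out = ma.bfactor_comparison(fr, -fr.msf + fr.msf.max() + 1.0)
        assert out.pearson_r == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self):
        msf = ma.FluctuationResult(msf=np.array([1.0, 2.0, 4.0, 3.0, 5.0]))
        b = np.array([2.0, 1.0, 5.0, 4.0, 4.5])
        out = ma.bfactor_comparison(msf, b)
        m, bb = msf.msf, b
        expected = (np.sum((m - m.mean()) * (bb - bb.mean()))
                    / np.sqrt(np.sum((m - m.mean()) ** 2) * np.sum((bb - bb.mean()) ** 2)))
        assert out.pearson_r == pytest.approx(expected)

    def test_scale_recovers_prefactor(self):
        msf = ma.FluctuationResult(msf=np.array([1.0, 2.0, 3.0, 4.0]))
        c_true = 0.7
        b = ma.B_FACTOR_PREFACTOR * c_true * msf.msf
        out = ma.bfactor_comparison(msf, b)
        assert out.scale == pytest.approx(c_true)

    def test_constant_b_rejected(self, lattice27_anm_modes):
        fr = ma.mean_square_fluctuations(lattice27_anm_modes)
        with pytest.raises(ValueError, match="constant"):
            ma.bfactor_comparison(fr, np.full(27, 5.0))


class TestModeAnimation:
    def test_zero_amplitude_frames_identical(self, lattice27, lattice27_anm_modes):
        ens = ma.mode_animation(lattice27, lattice27_anm_modes, 6, 0.0, 8)
        for fr in ens.frames:
            np.testing.assert_allclose(fr.coords, lattice27.coords)

    def test_frame_count(self, lattice27, lattice27_anm_modes):
        ens = ma.mode_animation(lattice27, lattice27_anm_modes, 6, 1.0, 7)
        assert ens.n_frames == 7

    def test_peak_displacement_equals_amplitude(self, lattice27, lattice27_anm_modes):
        amp = 2.5
        ens = ma.mode_animation(lattice27, lattice27_anm_modes, 6, amp, 20)
        max_disp = max(
            np.linalg.norm(fr.coords - lattice27.coords, axis=1).max()
            for fr in ens.frames)
        assert max_disp == pytest.approx(amp, abs=1e-6)

    def test_covers_both_directions(self, lattice27, lattice27_anm_modes):
        ens = ma.mode_animation(lattice27, lattice27_anm_modes, 6, 1.0, 8)
        shape = lattice27_anm_modes.mode_vector(6).reshape(-1, 3)
        proj = [float(np.sum((fr.coords - lattice27.coords) * shape))
                for fr in ens.frames]
        assert min(proj) < -1e-6 and max(proj) > 1e-6

    def test_zero_mode_rejected(self, lattice27, lattice27_anm_modes):
        with pytest.raises(ValueError, match="zero"):
            ma.mode_animation(lattice27, lattice27_anm_modes, 0, 1.0, 8)

    def test_gnm_rejected(self, lattice27, path3_gnm_modes):
        with pytest.raises(ValueError):
            ma.mode_animation(lattice27, path3_gnm_modes, 1, 1.0, 8)
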