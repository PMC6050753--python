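"""Superposition, PCA, clustering and autocorrelation against independent
oracles (quaternion superposition, dense eigensolver, naive agglomerative)."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_point_model

from fabscatter.models import Ensemble
from fabscatter.ensemble import (
    Selection,
    superpose,
    superpose_coords,
    pca,
    project,
    interpolate_pc,
    cluster,
    pairwise_rmsd_matrix,
    autocorrelation,
)


# ---------------------------------------------------------------- oracles
def quaternion_superpose_rmsd(mobile, reference):
    """Horn's quaternion method: independent of the SVD route."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)
    s = m.T @ r
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    evals, evecs = np.linalg.eigh(key)
    w, x, y, z = evecs[:, -1]
    rot = Rotation.from_quat([x, y, z, w]).as_matrix()
    moved = m @ rot.T
    return float(np.sqrt(np.mean(np.sum((moved - r) ** 2, axis=1))))


def naive_average_linkage(dmat, epsilon):
    """O(F^3)-ish agglomerative clustering, average linkage, stop at epsilon."""
    clusters = [[i] for i in range(len(dmat))]
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dmat[i, j] for i in clusters[a] for j in clusters[b]])
                if d < best[0]:
                    best = (d, a, b)
        if best[0] > epsilon:
            break
        d, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(dmat), dtype=int)
    for cid, members in enumerate(clusters):
        labels[sorted(members)] = cid
    return labels


def partitions_equal(labels_a, labels_b):
    seen = {}
    for la, lb in zip(labels_a, labels_b):
        if la in seen:
            if seen[la] != lb:
                return False
        else:
            seen[la] = lb
    return len(set(seen.values())) == len(seen)


def toy_ensemble(n_frames=10, n_atoms=30, scale=1.0, seed=5):
    rng = np.random.default_rng(seed)
    base = rng.normal(scale=8.0, size=(n_atoms, 3))
    coords = base[None] + rng.normal(scale=scale, size=(n_frames, n_atoms, 3))
    return Ensemble(topology=make_point_model(base), coordinates=coords)


# ------------------------------------------------------------ superposition
class TestSuperpose:
    def test_pure_rotation_removed(self, rng):
        coords = rng.normal(scale=10.0, size=(25, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved, rmsd = superpose_coords(coords @ rot.T, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(moved, coords, atol=1e-9)

    def test_identity(self, rng):
        coords = rng.normal(scale=10.0, size=(25, 3))
        moved, rmsd = superpose_coords(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_matches_quaternion_oracle(self, rng):
        a = rng.normal(scale=10.0, size=(100, 3))
        b = rng.normal(scale=10.0, size=(100, 3))
        _, rmsd = superpose_coords(a, b)
        assert rmsd == pytest.approx(quaternion_superpose_rmsd(a, b), abs=1e-9)

    def test_never_increases_rmsd(self, rng):
        for _ in range(5):
            a = rng.normal(scale=10.0, size=(40, 3))
            b = a + rng.normal(scale=2.0, size=(40, 3))
            before = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            _, after = superpose_coords(a, b)
            assert after <= before + 1e-12

    def test_too_few_atoms(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            superpose_coords(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))

    def test_collinear_selection_warns(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.warns(UserWarning, match="collinear"):
            superpose_coords(line, line + 1.0)

    def test_model_level_interface(self, rng):
        coords = rng.normal(scale=10.0, size=(20, 3))
        ref = make_point_model(coords)
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        mob = make_point_model(coords @ rot.T + 4.0)
        moved, rmsd = superpose(mob, ref, Selection())
        assert rmsd == pytest.approx(0.0, abs=1e-9)


# --------------------------------------------------------------------- PCA
class TestPCA:
    def test_single_displacement_gives_one_component(self):
        rng = np.random.default_rng(2)
        base = rng.normal(scale=8.0, size=(20, 3))
        v = np.array([1.0, 2.0, -0.5])
        frames = np.stack([base, base.copy()])
        frames[1, 7] += v
        ens = Ensemble(topology=make_point_model(base), coordinates=frames)
        # align on the atoms that do not move (residues 1-7, 9-20) so the
        # alignment is the identity and the displacement stays put
        align_sel = Selection.make(residue_ranges=[(1, 7), (9, 20)])
        res = pca(ens, align_selection=align_sel, analyze_selection=Selection(),
                  n_components=6)
        nonzero = res.eigenvalues > max(res.eigenvalues[0], 1e-30) * 1e-10
        assert nonzero.sum() == 1
        # the single eigenvector is the displacement direction on atom 7
        vec = res.eigenvectors[0].reshape(-1, 3)
        np.testing.assert_allclose(
            np.abs(vec[7] @ v / np.linalg.norm(v)), 1.0, atol=1e-10
        )
        np.testing.assert_allclose(np.delete(vec, 7, axis=0), 0.0, atol=1e-10)

    def test_identical_frames_zero_variance(self):
        ens = toy_ensemble(n_frames=4, scale=0.0)
        res = pca(ens, n_components=3)
        assert np.all(np.abs(res.eigenvalues) < 1e-18)

    def test_matches_dense_eigensolver_oracle(self):
        ens = toy_ensemble(n_frames=50, n_atoms=20, scale=1.5, seed=11)
        res = pca(ens, n_components=5)

        # oracle: quaternion alignment + explicit covariance loops + eigh
        coords = ens.coordinates.copy()
        aligned = [coords[0]]
        for i in range(1, 50):
            aligned.append(_quat_align(coords[i], coords[0]))
        mean = np.mean(aligned, axis=0)
        aligned = [_quat_align(a, mean) for a in aligned]
        x = np.array([a.reshape(-1) for a in aligned])
        mu = x.mean(axis=0)
        cov = np.zeros((60, 60))
        for row in x:
            d = row - mu
            cov += np.outer(d, d)
        cov /= 49
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        np.testing.assert_allclose(res.eigenvalues, evals[:5], rtol=1e-8, atol=1e-12)
        for k in range(5):
            dot = abs(res.eigenvectors[k] @ evecs[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_variance_fractions_sum_to_one(self):
        ens = toy_ensemble(n_frames=12, n_atoms=15, scale=1.0)
        res = pca(ens)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(res.eigenvalues > -1e-10)
        # orthonormality
        gram = res.eigenvectors @ res.eigenvectors.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_too_many_components(self):
        ens = toy_ensemble(n_frames=5, n_atoms=4)
        with pytest.raises(ValueError, match="exceeds"):
            pca(ens, n_components=13)


def _quat_align(mobile, reference):
    m0 = mobile.mean(axis=0)
    r0 = reference.mean(axis=0)
    m = mobile - m0
    r = reference - r0
    s = m.T @ r
    key = np.array([
        [s[0, 0] + s[1, 1] + s[2, 2], s[1, 2] - s[2, 1], s[2, 0] - s[0, 2], s[0, 1] - s[1, 0]],
        [s[1, 2] - s[2, 1], s[0, 0] - s[1, 1] - s[2, 2], s[0, 1] + s[1, 0], s[2, 0] + s[0, 2]],
        [s[2, 0] - s[0, 2], s[0, 1] + s[1, 0], -s[0, 0] + s[1, 1] - s[2, 2], s[1, 2] + s[2, 1]],
        [s[0, 1] - s[1, 0], s[2, 0] + s[0, 2], s[1, 2] + s[2, 1], -s[0, 0] - s[1, 1] + s[2, 2]],
    ])
    _, evecs = np.linalg.eigh(key)
    w, x, y, z = evecs[:, -1]
    rot = Rotation.from_quat([x, y, z, w]).as_matrix()
    return m @ rot.T + r0


# -------------------------------------------------------------- projection
class TestProject:
    @pytest.fixture
    def fitted(self):
        ens = toy_ensemble(n_frames=20, n_atoms=15, scale=1.2, seed=9)
        return ens, pca(ens, n_components=4)

    def test_mean_projects_to_zero(self, fitted):
        ens, res = fitted
        mean_model = ens.topology.with_coords(res.mean_full)
        scores = project(res, mean_model)
        np.testing.assert_allclose(scores, 0.0, atol=1e-8)

    def test_training_frame_self_consistency(self, fitted):
        ens, res = fitted
        scores = project(res, ens.frame(3))
        np.testing.assert_allclose(scores, res.projections[3], atol=1e-8)

    def test_displaced_mean_recovers_amplitude(self, fitted):
        ens, res = fitted
        a = 2.5
        disp = res.mean_full.copy()
        disp[res.analyze_indices] = (
            res.mean_coords + a * res.eigenvectors[0]
        ).reshape(-1, 3)
        scores = project(res, ens.topology.with_coords(disp))
        np.testing.assert_allclose(scores, [a, 0, 0, 0], atol=1e-8)

    def test_atom_mismatch_raises(self, fitted, rng):
        _, res = fitted
        wrong = make_point_model(rng.normal(size=(7, 3)))
        with pytest.raises(ValueError, match="atoms"):
            project(res, wrong)


class TestInterpolatePC:
    def test_amplitude_zero_is_mean(self):
        ens = toy_ensemble(n_frames=10, n_atoms=12, scale=1.0)
        res = pca(ens, n_components=2)
        interp = interpolate_pc(res, 1, [0.0])
        np.testing.assert_allclose(interp.coordinates[0], res.mean_full, atol=1e-12)

    def test_symmetric_amplitudes(self):
        ens = toy_ensemble(n_frames=10, n_atoms=12, scale=1.0)
        res = pca(ens, n_components=2)
        interp = interpolate_pc(res, 1, [-3.0, 3.0])
        mid = 0.5 * (interp.coordinates[0] + interp.coordinates[1])
        np.testing.assert_allclose(mid, res.mean_full, atol=1e-10)

    def test_projection_round_trip(self):
        ens = toy_ensemble(n_frames=10, n_atoms=12, scale=1.0)
        res = pca(ens, n_components=3)
        interp = interpolate_pc(res, 2, [1.75])
        scores = project(res, interp.frame(0))
        np.testing.assert_allclose(scores, [0.0, 1.75, 0.0], atol=1e-8)


# -------------------------------------------------------------- clustering
class TestCluster:
    def test_identical_frames_single_cluster(self):
        ens = toy_ensemble(n_frames=6, scale=0.0)
        cs = cluster(ens, epsilon=2.0)
        assert cs.n_clusters == 1
        assert cs.representatives == [0]  # lowest index on ties

    def test_two_separated_groups(self, rng):
        base = rng.normal(scale=8.0, size=(25, 3))
        open_conf = base.copy()
        open_conf[:12] += [15.0, 0, 0]
        frames = []
        for i in range(8):
            src = base if i % 2 == 0 else open_conf
            frames.append(src + rng.normal(scale=0.2, size=(25, 3)))
        ens = Ensemble(topology=make_point_model(base), coordinates=np.array(frames))
        cs = cluster(ens, epsilon=2.0)
        assert cs.n_clusters == 2
        assert partitions_equal(cs.labels, np.array([0, 1] * 4))

    def test_matches_naive_agglomerative_oracle(self):
        ens = toy_ensemble(n_frames=30, n_atoms=20, scale=2.5, seed=21)
        cs = cluster(ens, epsilon=2.0)
        oracle = naive_average_linkage(cs.rmsd_matrix, 2.0)
        assert partitions_equal(cs.labels, oracle)

    def test_permutation_equivariance(self):
        ens = toy_ensemble(n_frames=12, n_atoms=20, scale=2.5, seed=33)
        cs = cluster(ens, epsilon=2.0)
        perm = np.random.default_rng(0).permutation(12)
        permuted = Ensemble(
            topology=ens.topology, coordinates=ens.coordinates[perm]
        )
        cs_p = cluster(permuted, epsilon=2.0)
        assert partitions_equal(cs_p.labels, cs.labels[perm])

    def test_representative_minimizes_mean_rmsd(self):
        ens = toy_ensemble(n_frames=9, n_atoms=20, scale=1.0, seed=4)
        cs = cluster(ens, epsilon=50.0)  # everything in one cluster
        assert cs.n_clusters == 1
        dmat = cs.rmsd_matrix
        means = dmat.sum(axis=1) / (len(dmat) - 1)
        assert cs.representatives[0] == int(np.argmin(means))

    def test_epsilon_must_be_positive(self):
        ens = toy_ensemble(n_frames=3)
        with pytest.raises(ValueError):
            cluster(ens, epsilon=0.0)

    def test_rmsd_matrix_is_best_fit(self):
        ens = toy_ensemble(n_frames=4, n_atoms=20, scale=1.0, seed=8)
        dmat = pairwise_rmsd_matrix(ens)
        _, expected = superpose_coords(ens.coordinates[2], ens.coordinates[1])
        assert dmat[1, 2] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_array_equal(dmat, dmat.T)


# ---------------------------------------------------------- autocorrelation
class TestAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        acf = autocorrelation(rng.normal(size=100))
        assert acf[0] == pytest.approx(1.0)

    def test_alternating_series_lag_one(self):
        series = np.array([1.0, -1.0] * 50)
        acf = autocorrelation(series, max_lag=2)
        assert acf[1] == pytest.approx(-1.0)

    def test_ar1_recovers_phi(self):
        phi = 0.8
        rng = np.random.default_rng(123)
        n = 100_000
        x = np.empty(n)
        x[0] = rng.normal()
        for t in range(1, n):
            x[t] = phi * x[t - 1] + rng.normal()
        acf = autocorrelation(x, max_lag=5)
        assert acf[1] == pytest.approx(phi, abs=0.01)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            autocorrelation(np.ones(10))

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            autocorrelation(np.array([1.0]))
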