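"""RMSD/distance/contact observables, DCCM, PCA, state-space projection,
and crystal-pair displacement."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import pixelmd as px
from pixelmd.topology import ConformationalEnsemble, Topology


def ca_topology(n):
    return Topology(
        atom_names=["CA"] * n,
        elements=["C"] * n,
        residue_indices=np.arange(1, n + 1),
        residue_names=["ALA"] * n,
        chain_ids=["A"] * n,
    )


def make_ens(coords, topo=None):
    coords = np.asarray(coords, dtype=float)
    if topo is None:
        topo = ca_topology(coords.shape[1])
    return ConformationalEnsemble(
        coords=coords,
        times=10.0 * np.arange(1, coords.shape[0] + 1),
        topology=topo,
    )


class TestRmsdSeries:
    def test_identical_frames_give_zero(self):
        ref = np.random.default_rng(0).normal(size=(5, 3))
        ens = make_ens(np.repeat(ref[None], 4, axis=0))
        s = px.rmsd_series(ens, ref)
        assert np.allclose(s.values, 0.0, atol=1e-9)

    def test_hand_worked_sqrt2_without_superposition(self):
        # two atoms each displaced by 2 A along x: RMSD = sqrt((4+4)/2) = 2;
        # one atom displaced 2, one 0: RMSD = sqrt(4/2) = sqrt(2)
        ref = np.array([[0.0, 0, 0], [0, 5.0, 0]])
        moved = ref.copy()
        moved[0, 0] += 2.0
        ens = make_ens(moved[None])
        s = px.rmsd_series(ens, ref, superpose=False)
        assert s.values[0] == pytest.approx(np.sqrt(2.0))

    def test_superposition_removes_rigid_motion(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(scale=4.0, size=(8, 3))
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        moved = ref @ rot.T + np.array([3.0, -2.0, 7.0])
        ens = make_ens(moved[None])
        fitted = px.rmsd_series(ens, ref, superpose=True)
        raw = px.rmsd_series(ens, ref, superpose=False)
        assert fitted.values[0] == pytest.approx(0.0, abs=1e-9)
        assert raw.values[0] > 1.0

    def test_empty_selection_rejected(self):
        ref = np.zeros((4, 3))
        ens = make_ens(ref[None])
        with pytest.raises(ValueError):
            px.rmsd_series(ens, ref, selection=np.array([], dtype=int))


class TestPairDistances:
    def test_three_four_five_triangle(self):
        coords = np.array([[[0.0, 0, 0], [3.0, 4.0, 0]]])
        ens = make_ens(coords)
        s = px.pair_distance_series(ens, 1, 2)
        assert s.values[0] == pytest.approx(5.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        base = rng.normal(scale=5.0, size=(6, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        moved = base @ rot.T + 11.0
        ens = make_ens(np.stack([base, moved]))
        s = px.pair_distance_series(ens, 2, 5)
        assert s.values[0] == pytest.approx(s.values[1], abs=1e-9)

    def _two_residue_sidechain_topo(self):
        return Topology(
            atom_names=["CA", "CB", "CA", "CB"],
            elements=["C", "C", "C", "C"],
            residue_indices=[1, 1, 2, 2],
            residue_names=["ALA", "ALA", "ALA", "ALA"],
            chain_ids=["A"] * 4,
        )

    def test_closest_heavy_never_exceeds_ca_ca(self):
        topo = self._two_residue_sidechain_topo()
        rng = np.random.default_rng(4)
        coords = rng.normal(scale=5.0, size=(10, 4, 3))
        ens = make_ens(coords, topo)
        ca = px.pair_distance_series(ens, 1, 2, metric="CA-CA")
        ch = px.pair_distance_series(ens, 1, 2, metric="closest-heavy")
        assert np.all(ch.values <= ca.values + 1e-12)

    def test_closest_heavy_hand_example(self):
        topo = self._two_residue_sidechain_topo()
        # CB of residue 1 sits 2 A from CB of residue 2; CAs are 10 A apart
        coords = np.array([[
            [0.0, 0, 0], [4.0, 0, 0], [10.0, 0, 0], [6.0, 0, 0],
        ]])
        ens = make_ens(coords, topo)
        s = px.pair_distance_series(ens, 1, 2, metric="closest-heavy")
        assert s.values[0] == pytest.approx(2.0)

    def test_unknown_metric_rejected(self):
        ens = make_ens(np.zeros((1, 2, 3)) + np.arange(2)[None, :, None])
        with pytest.raises(ValueError):
            px.pair_distance_series(ens, 1, 2, metric="geodesic")

    def test_ca_only_topology_rejects_closest_heavy(self):
        ens = make_ens(np.arange(6.0).reshape(1, 2, 3))
        with pytest.raises(ValueError):
            px.pair_distance_series(ens, 1, 2, metric="closest-heavy")


class TestContacts:
    def test_fraction_hand_example(self):
        s = px.DistanceSeries(
            times=np.arange(4.0), values=np.array([3.0, 4.4, 4.6, 10.0]),
            metric="CA-CA", threshold=4.5,
        )
        assert px.contact_fraction(s) == pytest.approx(0.5)

    def test_threshold_is_strict(self):
        s = px.DistanceSeries(
            times=np.arange(2.0), values=np.array([4.5, 4.499]),
            metric="CA-CA", threshold=4.5,
        )
        assert px.contact_fraction(s) == pytest.approx(0.5)

    def test_empty_series_rejected(self):
        s = px.DistanceSeries(times=np.array([]), values=np.array([]), metric="CA-CA")
        with pytest.raises(ValueError):
            px.contact_fraction(s)

    def test_negative_distances_rejected(self):
        with pytest.raises(ValueError):
            px.DistanceSeries(
                times=np.arange(1.0), values=np.array([-0.1]), metric="CA-CA"
            )


def brute_force_dccm(coords):
    """Direct loop implementation of C_ij = <dr_i.dr_j>/sqrt(<dr_i^2><dr_j^2>)."""
    f, r, _ = coords.shape
    mean = coords.mean(axis=0)
    dr = coords - mean
    c = np.empty((r, r))
    for i in range(r):
        for j in range(r):
            num = np.mean([dr[t, i] @ dr[t, j] for t in range(f)])
            di = np.mean([dr[t, i] @ dr[t, i] for t in range(f)])
            dj = np.mean([dr[t, j] @ dr[t, j] for t in range(f)])
            c[i, j] = num / np.sqrt(di * dj)
    return c


class TestDccm:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(3, 4, 3))
        m = px.dccm(make_ens(coords)).matrix
        oracle = brute_force_dccm(coords)
        assert np.abs(m - oracle).max() < 1e-12

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(6)
        m = px.dccm(make_ens(rng.normal(size=(50, 8, 3)))).matrix
        assert np.allclose(m, m.T, atol=1e-12)
        assert np.allclose(np.diag(m), 1.0)
        assert np.all(np.abs(m) <= 1.0 + 1e-12)

    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(7)
        disp = rng.normal(size=(100, 1, 3))
        base = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        coords = base[None] + np.concatenate([disp, disp], axis=1)
        m = px.dccm(make_ens(coords))
        assert m.value(1, 2) == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_pair(self):
        rng = np.random.default_rng(8)
        disp = rng.normal(size=(100, 1, 3))
        base = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        coords = base[None] + np.concatenate([disp, -disp], axis=1)
        m = px.dccm(make_ens(coords))
        assert m.value(1, 2) == pytest.approx(-1.0, abs=1e-12)

    def test_immobile_residue_warns_and_nans(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(20, 3, 3))
        coords[:, 2] = np.array([5.0, 5.0, 5.0])  # frozen residue
        with pytest.warns(UserWarning):
            m = px.dccm(make_ens(coords))
        assert np.isnan(m.value(1, 3)) and np.isnan(m.value(3, 3))
        assert np.isfinite(m.value(1, 2))

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            px.dccm(make_ens(np.zeros((1, 3, 3)) + np.arange(3)[None, :, None]))

    def test_planted_block_recovered(self, block_dccm):
        # residues 1-5 and 20-24 share a planted cross-correlation of 0.8;
        # with 10,000 frames the estimate lands within +-0.05
        spec, m = block_dccm
        block = spec.correlation_blocks[0]
        cross = [
            m.value(i, j)
            for i in range(block.range_a[0], block.range_a[1] + 1)
            for j in range(block.range_b[0], block.range_b[1] + 1)
        ]
        assert np.mean(cross) == pytest.approx(0.8, abs=0.05)
        # a residue pair outside both blocks stays near zero
        background = [m.value(10, 28), m.value(11, 29), m.value(12, 27)]
        assert np.abs(np.mean(background)) < 0.1


class TestPca:
    def test_planted_collective_mode_recovered(self):
        # all residues oscillate along one random 3R-direction: PC1 must
        # align with it (|cos| > 0.99) and dominate the spectrum
        rng = np.random.default_rng(10)
        r = 12
        base = rng.normal(scale=8.0, size=(r, 3))
        direction = rng.normal(size=3 * r)
        direction /= np.linalg.norm(direction)
        amp = rng.normal(scale=2.0, size=(300, 1))
        noise = rng.normal(scale=0.05, size=(300, 3 * r))
        coords = base.reshape(-1) + amp * direction + noise
        ens = make_ens(coords.reshape(300, r, 3))
        res = px.pca_modes(ens)
        cos = np.abs(res.eigenvectors[:, 0] @ direction)
        assert cos > 0.99
        assert res.explained_fraction[0] > 0.9

    def test_eigen_identities(self):
        rng = np.random.default_rng(11)
        ens = make_ens(rng.normal(size=(60, 4, 3)))
        res = px.pca_modes(ens)
        v = res.eigenvectors
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-10)
        # projection variance equals the eigenvalue, mode by mode
        proj_var = res.projections.var(axis=0, ddof=1)
        assert np.allclose(proj_var, res.eigenvalues, atol=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.explained_fraction.sum() == pytest.approx(1.0)

    def test_pc1_vectors_scale_with_sqrt_lambda(self):
        rng = np.random.default_rng(12)
        ens = make_ens(rng.normal(size=(50, 3, 3)))
        res = px.pca_modes(ens)
        expected = res.eigenvectors[:, 0].reshape(3, 3) * np.sqrt(res.eigenvalues[0])
        assert np.allclose(res.pc1_vectors, expected)
        assert np.allclose(
            res.pc1_amplitudes, np.linalg.norm(expected, axis=1)
        )

    def test_isotropic_noise_has_flat_spectrum(self):
        rng = np.random.default_rng(13)
        ens = make_ens(rng.normal(size=(20_000, 2, 3)))
        res = px.pca_modes(ens)
        assert res.eigenvalues[0] / res.eigenvalues[-1] < 1.2

    def test_rank_deficient_warns(self):
        rng = np.random.default_rng(14)
        with pytest.warns(UserWarning):
            px.pca_modes(make_ens(rng.normal(size=(5, 10, 3))))

    def test_n_modes_truncation(self):
        rng = np.random.default_rng(15)
        ens = make_ens(rng.normal(size=(40, 5, 3)))
        res = px.pca_modes(ens, n_modes=2)
        assert res.eigenvalues.shape == (2,)
        assert res.projections.shape == (40, 2)


class TestStateSpace:
    def test_density_normalized(self):
        rng = np.random.default_rng(16)
        density, xe, ye = px.state_space_projection(
            rng.random(500), rng.random(500), bins=20
        )
        assert density.sum() == pytest.approx(1.0)
        assert density.shape == (20, 20)

    def test_two_blobs_clustered_apart(self):
        rng = np.random.default_rng(17)
        x = np.concatenate([rng.normal(1, 0.1, 100), rng.normal(8, 0.1, 100)])
        y = np.concatenate([rng.normal(5, 0.1, 100), rng.normal(20, 0.1, 100)])
        _, _, _, labels = px.state_space_projection(x, y, cluster=True, seed=0)
        assert len(np.unique(labels[:100])) == 1
        assert len(np.unique(labels[100:])) == 1
        assert labels[0] != labels[150]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            px.state_space_projection(np.zeros(5), np.zeros(6))


class TestCrystalDisplacement:
    def _structures(self, move=6.0, n=20, seed=18):
        rng = np.random.default_rng(seed)
        topo = ca_topology(n)
        a = rng.normal(scale=6.0, size=(n, 3))
        b = a.copy()
        b[9] += np.array([move, 0.0, 0.0])  # residue 10 moves by `move` A
        # then hide the correspondence under a rigid motion of B
        rot = Rotation.random(random_state=seed).as_matrix()
        b = b @ rot.T + np.array([4.0, -3.0, 12.0])
        return a, topo, b, topo

    def test_known_displacement_recovered(self):
        a, ta, b, tb = self._structures(move=6.0)
        align = [r for r in range(1, 21) if r != 10]
        d = px.crystal_pair_displacement(a, ta, b, tb, align, residue=10)
        assert d == pytest.approx(6.0, abs=1e-6)

    def test_zero_displacement_for_identical_structures(self):
        a, ta, b, tb = self._structures(move=0.0)
        d = px.crystal_pair_displacement(a, ta, b, tb, list(range(1, 21)), 10)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_alignment_uses_shared_residues_only(self):
        # structure B lacks residues 18-20: alignment must still work on
        # the intersection and report the same displacement
        a, ta, b, tb = self._structures(move=5.0)
        tb_short = ca_topology(17)
        align = [r for r in range(1, 18) if r != 10]
        d = px.crystal_pair_displacement(
            a, ta, b[:17], tb_short, [r for r in range(1, 21) if r != 10], 10
        )
        ref = px.crystal_pair_displacement(a, ta, b[:17], tb_short, align, 10)
        assert d == pytest.approx(ref, abs=1e-9)

    def test_missing_target_residue_raises(self):
        a, ta, b, tb = self._structures()
        tb_short = ca_topology(9)
        with pytest.raises(KeyError):
            px.crystal_pair_displacement(
                a, ta, b[:9], tb_short, list(range(1, 9)), residue=15
            )

    def test_too_few_shared_residues_rejected(self):
        a, ta, b, tb = self._structures()
        with pytest.raises(ValueError):
            px.crystal_pair_displacement(a, ta, b, tb, [1, 2], residue=10)
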