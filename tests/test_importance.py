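"""Local surrogate explanations: perturbation, fitting, binarization,
residue aggregation, and planted-signal recovery."""

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

import pixelmd as px
from pixelmd.importance import fit_local_surrogate, kernel_width, perturb_samples


def small_image(side=4, n_atoms=13, seed=0):
    rng = np.random.default_rng(seed)
    img = np.zeros((side, side, 3), dtype=np.uint8)
    flat = img.reshape(-1, 3)
    flat[:n_atoms] = rng.integers(1, 255, size=(n_atoms, 3))
    mean = flat.astype(float) + 0.3
    return img, mean.reshape(side, side, 3), n_atoms


class TestPerturbation:
    def test_shapes_and_dtypes(self):
        img, mean, n_atoms = small_image()
        imgs, presence, weights = perturb_samples(img, n_atoms, 200, 0, mean)
        assert imgs.shape == (200, 4, 4, 3) and imgs.dtype == np.uint8
        assert presence.shape == (200, n_atoms)
        assert weights.shape == (200,)

    def test_anchor_row_is_unperturbed(self):
        img, mean, n_atoms = small_image()
        imgs, presence, weights = perturb_samples(img, n_atoms, 100, 1, mean)
        assert np.all(presence[0] == 1)
        assert np.array_equal(imgs[0], img)
        assert weights[0] == 1.0

    def test_weights_match_kernel_formula(self):
        img, mean, n_atoms = small_image()
        sigma = 2.5
        _, presence, weights = perturb_samples(img, n_atoms, 300, 2, mean, sigma=sigma)
        d2 = (1 - presence).sum(axis=1)
        assert np.allclose(weights, np.exp(-d2 / sigma ** 2))

    def test_masked_pixels_take_mean_value(self):
        img, mean, n_atoms = small_image()
        imgs, presence, _ = perturb_samples(img, n_atoms, 100, 3, mean)
        flat = imgs.reshape(100, -1, 3)
        mean_q = np.clip(np.rint(mean.reshape(-1, 3)[:n_atoms]), 0, 255)
        for k in (1, 2):
            masked = np.flatnonzero(presence[k] == 0)
            assert np.array_equal(flat[k, masked], mean_q[masked].astype(np.uint8))
            kept = np.flatnonzero(presence[k] == 1)
            assert np.array_equal(flat[k, kept], img.reshape(-1, 3)[kept])

    def test_padding_pixels_never_touched(self):
        img, mean, n_atoms = small_image()
        imgs, _, _ = perturb_samples(img, n_atoms, 100, 4, mean)
        assert np.all(imgs.reshape(100, -1, 3)[:, n_atoms:] == 0)

    def test_seed_reproducible(self):
        img, mean, n_atoms = small_image()
        a = perturb_samples(img, n_atoms, 100, 7, mean)
        b = perturb_samples(img, n_atoms, 100, 7, mean)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_few_perturbations_warn(self):
        img, mean, n_atoms = small_image()
        with pytest.warns(UserWarning):
            perturb_samples(img, n_atoms, 10, 0, mean)

    def test_default_kernel_width(self):
        assert kernel_width(100) == pytest.approx(7.5)


class TestSurrogateFit:
    def test_recovers_exact_linear_function(self):
        # target generated by a known linear rule -> coefficients recovered
        rng = np.random.default_rng(0)
        presence = (rng.random((400, 12)) < 0.5).astype(int)
        presence[0] = 1
        beta = rng.normal(size=12)
        target = 0.3 + presence @ beta
        weights = np.exp(-(1 - presence).sum(axis=1) / kernel_width(12) ** 2)
        coef = fit_local_surrogate(presence, target, weights)
        assert np.abs(coef - beta).max() < 1e-6

    def test_matches_sklearn_weighted_oracle(self):
        rng = np.random.default_rng(1)
        presence = (rng.random((500, 10)) < 0.5).astype(int)
        target = rng.random(500)  # noisy, not exactly linear
        weights = np.exp(-(1 - presence).sum(axis=1) / 5.0 ** 2)
        coef = fit_local_surrogate(presence, target, weights)
        oracle = LinearRegression().fit(presence, target, sample_weight=weights)
        assert np.abs(coef - oracle.coef_).max() < 1e-6

    def test_weights_matter(self):
        rng = np.random.default_rng(2)
        presence = (rng.random((300, 8)) < 0.5).astype(int)
        target = rng.random(300)
        uniform = fit_local_surrogate(presence, target, np.ones(300))
        skewed_w = np.exp(-(1 - presence).sum(axis=1) / 1.5 ** 2)
        skewed = fit_local_surrogate(presence, target, skewed_w)
        assert not np.allclose(uniform, skewed)

    def test_constant_design_rejected(self):
        presence = np.ones((50, 5), dtype=int)
        with pytest.raises(ValueError):
            fit_local_surrogate(presence, np.ones(50), np.ones(50))

    def test_collinear_design_falls_back_with_warning(self):
        rng = np.random.default_rng(3)
        base = (rng.random((100, 3)) < 0.5).astype(int)
        presence = np.hstack([base, base[:, :1]])  # duplicated column
        with pytest.warns(UserWarning):
            coef = fit_local_surrogate(
                presence, rng.random(100), np.ones(100), ridge=0.0
            )
        assert np.all(np.isfinite(coef))


class TestBinarize:
    def test_top_m_by_magnitude(self):
        coef = np.array([0.1, -3.0, 0.5, 2.0, -0.2])
        out = px.binarize_importance(coef, m=2)
        assert out.tolist() == [0, 1, 0, 1, 0]

    def test_default_fraction_of_pixels(self):
        coef = np.arange(100, dtype=float)
        out = px.binarize_importance(coef)  # 10% of 100 -> 10 pixels
        assert out.sum() == 10
        assert np.all(out[-10:] == 1)

    def test_ties_break_toward_lower_index(self):
        coef = np.array([1.0, 1.0, 1.0, 0.5])
        out = px.binarize_importance(coef, m=2)
        assert out.tolist() == [1, 1, 0, 0]

    def test_at_least_one_pixel_marked(self):
        out = px.binarize_importance(np.array([0.0, 0.0, 0.1]), top_fraction=0.01)
        assert out.sum() == 1

    def test_m_capped_at_pixel_count(self):
        out = px.binarize_importance(np.array([1.0, 2.0]), m=10)
        assert out.sum() == 2


def tiny_topology():
    # 2 residues x 2 atoms
    from pixelmd.topology import Topology
    return Topology(
        atom_names=["CA", "CB"] * 2,
        elements=["C"] * 4,
        residue_indices=[1, 1, 2, 2],
        residue_names=["ALA"] * 4,
        chain_ids=["A"] * 4,
    )


def expl(bits, cid=0):
    bits = np.asarray(bits, dtype=np.int8)
    return px.SurrogateExplanation(
        conformation_id=cid, pixel_importance=bits,
        coefficients=bits.astype(float), n_perturbations=100, kernel_sigma=1.5,
    )


class TestAggregation:
    def test_hand_worked_average(self):
        topo = tiny_topology()
        # residue 1 atoms marked (1,0) and (1,1); residue 2 atoms (0,0) and (1,0)
        table = px.aggregate_residue_scores(
            [expl([1, 0, 0, 1]), expl([1, 1, 1, 0], cid=1)], topo
        )
        assert table.score_of(1) == pytest.approx(0.75)
        assert table.score_of(2) == pytest.approx(0.5)

    def test_scores_bounded(self):
        topo = tiny_topology()
        table = px.aggregate_residue_scores([expl([1, 1, 1, 1])], topo)
        assert np.all((table.scores >= 0) & (table.scores <= 1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            px.aggregate_residue_scores([], tiny_topology())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            px.aggregate_residue_scores([expl([1, 0])], tiny_topology())

    def test_nonbinary_explanation_rejected(self):
        with pytest.raises(ValueError):
            expl([0, 2, 0, 0])

    def test_table_frame_is_rank_sorted(self):
        topo = tiny_topology()
        table = px.aggregate_residue_scores([expl([0, 0, 1, 1])], topo)
        df = table.to_frame()
        assert df.loc[df["rank"] == 1, "residue"].item() == 2


class TestTopK:
    def make_table(self):
        return px.ResidueImportanceTable(
            residue_ids=np.array([1, 2, 3, 4]),
            scores=np.array([0.2, 0.9, 0.9, 0.1]),
            n_conformations=5,
        )

    def test_ordering_and_ties(self):
        assert px.top_k_residues(self.make_table(), 3) == [2, 3, 1]

    def test_k_validation(self):
        with pytest.raises(ValueError):
            px.top_k_residues(self.make_table(), 0)
        with pytest.raises(ValueError):
            px.top_k_residues(self.make_table(), 5)

    def test_missing_residue_lookup_raises(self):
        with pytest.raises(KeyError):
            self.make_table().score_of(99)


class TestExplainDataset:
    def test_scores_valid_and_deterministic(self, trained_separated):
        dataset, clf = trained_separated
        t1, e1 = px.explain_dataset(clf, dataset, n_per_state=3,
                                    n_perturbations=200, seed=11)
        t2, _ = px.explain_dataset(clf, dataset, n_per_state=3,
                                   n_perturbations=200, seed=11)
        assert np.array_equal(t1.scores, t2.scores)
        assert np.all((t1.scores >= 0) & (t1.scores <= 1))
        assert len(e1) == 6
        assert t1.n_conformations == 6

    def test_planted_residues_recovered(self, planted_recovery):
        # across 3 independent seeds, at least 8 of the 10 planted residues
        # appear in the top-10 of the aggregated importance table
        for run in planted_recovery:
            assert run["hits"] >= 8, (
                f"seed {run['seed']}: only {run['hits']}/10 planted residues "
                f"in top-10 ({sorted(run['top10'])} vs {sorted(run['planted'])})"
            )

    def test_planted_residues_score_above_background(self, planted_recovery):
        for run in planted_recovery:
            table = run["table"]
            planted = run["planted"]
            p_scores = [table.score_of(r) for r in planted]
            bg = [table.score_of(r) for r in table.residue_ids
                  if r not in planted]
            assert np.mean(p_scores) > np.mean(bg)
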