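import numpy as np
import pytest

from pgxpop import ari, evaluate_clustering, kmeans, nmi, pca, scale_genotypes, silhouette
from pgxpop.cohort import MISSING, DosageMatrix
from pgxpop.structure import StructureError


def _dosages(values, rsids=None):
    values = np.asarray(values)
    rsids = rsids or [f"rs{i}" for i in range(values.shape[1])]
    return DosageMatrix(values=values, rsids=rsids)


class TestScaling:
    def test_constant_het_column_centers_to_zero(self):
        d = _dosages(np.ones((5, 1), dtype=int))
        sc = scale_genotypes(d)
        assert np.allclose(sc.values, 0.0)

    def test_monomorphic_dropped_and_recorded(self):
        vals = np.zeros((4, 2), dtype=int)
        vals[:, 1] = [0, 1, 1, 2]
        sc = scale_genotypes(_dosages(vals))
        assert sc.dropped == ["rs0"]
        assert sc.rsids == ["rs1"]

    def test_missing_mean_imputed_finite(self):
        vals = np.array([[0], [1], [2], [MISSING]], dtype=int)
        sc = scale_genotypes(_dosages(vals))
        assert np.isfinite(sc.values).all()
        assert sc.values[3, 0] == pytest.approx(0.0)  # imputed to column mean

    def test_all_monomorphic_errors(self):
        with pytest.raises(StructureError):
            scale_genotypes(_dosages(np.full((3, 4), 2, dtype=int)))

    def test_two_population_mean_shift_survives_scaling(self, panel):
        from pgxpop import sample_balding_nichols

        coh = sample_balding_nichols(
            np.full(24, 0.5), {"A": 0.2, "B": 0.2}, {"A": 150, "B": 150}, 3, panel
        )
        sc = scale_genotypes(coh.dosage_matrix())
        ga = sc.values[np.asarray(coh.populations) == "A"].mean(axis=0)
        gb = sc.values[np.asarray(coh.populations) == "B"].mean(axis=0)
        assert np.abs(ga - gb).max() > 0.5


class TestPca:
    def test_single_variable_locus_single_component(self):
        vals = np.zeros((6, 3), dtype=int)
        vals[:, 1] = [0, 0, 1, 1, 2, 2]
        sc = scale_genotypes(_dosages(vals))
        with pytest.warns(UserWarning, match="rank"):
            res = pca(sc, n_components=2)
        assert res.eigenvalues.shape == (1,)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        vals = rng.integers(0, 3, size=(40, 10))
        sc = scale_genotypes(_dosages(vals))
        res = pca(sc, n_components=len(sc.rsids))
        total = sc.values.var(axis=0, ddof=1).sum()
        assert res.eigenvalues.sum() == pytest.approx(total, abs=1e-8)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_reconstruction_within_rank(self, rng):
        vals = rng.integers(0, 3, size=(25, 8))
        sc = scale_genotypes(_dosages(vals))
        k = len(sc.rsids)
        res = pca(sc, n_components=k)
        recon = res.scores @ res.loadings.T
        assert np.allclose(recon, sc.values, atol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        vals = rng.integers(0, 3, size=(30, 6))
        sc = scale_genotypes(_dosages(vals))
        a, b = pca(sc, 2), pca(sc, 2)
        assert np.array_equal(a.scores, b.scores)
        for c in range(2):
            j = np.argmax(np.abs(a.loadings[:, c]))
            assert a.loadings[j, c] > 0

    def test_high_drift_population_separates_on_pc1(self, panel):
        """Strongly drifted group vs two similar groups: PC1 carries the
        split, echoing continental-scale structure."""
        from pgxpop import sample_balding_nichols

        coh = sample_balding_nichols(
            np.full(24, 0.5),
            {"EURlike": 0.05, "EASlike": 0.15, "AFRlike": 0.45},
            {"EURlike": 200, "EASlike": 200, "AFRlike": 200},
            11,
            panel,
        )
        res = pca(scale_genotypes(coh.dosage_matrix()), 2)
        pops = np.asarray(coh.populations)
        cent = {p: res.scores[pops == p].mean(axis=0) for p in np.unique(pops)}
        sep1 = abs(cent["AFRlike"][0] - (cent["EURlike"][0] + cent["EASlike"][0]) / 2)
        sep2 = abs(cent["AFRlike"][1] - (cent["EURlike"][1] + cent["EASlike"][1]) / 2)
        assert sep1 > sep2


class TestClusteringMetrics:
    def test_kmeans_single_cluster(self, rng):
        pts = rng.normal(size=(10, 2))
        assert set(kmeans(pts, 1, seed=0)) == {0}

    def test_kmeans_separable_blobs(self, rng):
        pts = np.vstack(
            [rng.normal(c, 0.05, size=(30, 2)) for c in ((0, 0), (10, 0), (0, 10))]
        )
        truth = np.repeat([0, 1, 2], 30)
        labels = kmeans(pts, 3, seed=1)
        assert ari(labels, truth) == 1.0

    def test_kmeans_deterministic(self, rng):
        pts = rng.normal(size=(50, 2))
        a = kmeans(pts, 3, seed=9)
        b = kmeans(pts, 3, seed=9)
        assert np.array_equal(a, b)

    def test_kmeans_k_exceeds_n(self, rng):
        with pytest.raises(StructureError):
            kmeans(rng.normal(size=(3, 2)), 5, seed=0)

    def test_silhouette_hand_computed(self):
        pts = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], float)
        labels = [0, 0, 1, 1]
        # a = 1; b = mean(10, sqrt(101)) ~ 10.025; s ~ 0.9002
        assert silhouette(pts, labels) == pytest.approx(0.9002, abs=2e-4)

    def test_silhouette_tight_distant_blobs(self, rng):
        pts = np.vstack(
            [rng.normal((0, 0), 0.01, (20, 2)), rng.normal((50, 0), 0.01, (20, 2))]
        )
        assert silhouette(pts, [0] * 20 + [1] * 20) > 0.9

    def test_silhouette_random_labels_near_zero(self, rng):
        pts = rng.normal(size=(200, 2))
        labels = rng.integers(0, 2, 200)
        assert abs(silhouette(pts, labels)) < 0.1

    def test_silhouette_single_cluster_errors(self, rng):
        with pytest.raises(StructureError):
            silhouette(rng.normal(size=(5, 2)), [0] * 5)

    def test_ari_nmi_identical_labelings(self):
        assert ari([0, 1, 2, 0], [2, 0, 1, 2]) == 1.0
        assert nmi([0, 1, 2, 0], [2, 0, 1, 2]) == 1.0

    def test_ari_nmi_hand_example(self):
        # pair-count arithmetic: contingency all-ones 2x2 -> ARI -0.5, MI 0
        assert ari([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)
        assert nmi([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_label_permutation_invariance(self, rng):
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 3, 60)
        remap = {0: 2, 1: 0, 2: 1}
        b2 = np.vectorize(remap.get)(b)
        assert ari(a, b) == pytest.approx(ari(a, b2))
        assert nmi(a, b) == pytest.approx(nmi(a, b2))

    def test_length_mismatch_rejected(self):
        with pytest.raises(StructureError):
            ari([0, 1], [0, 1, 2])


def test_evaluate_clustering_composition(panel):
    from pgxpop import sample_balding_nichols

    coh = sample_balding_nichols(
        np.full(24, 0.5), {"A": 0.05, "B": 0.45}, {"A": 100, "B": 100}, 21, panel
    )
    res = pca(scale_genotypes(coh.dosage_matrix()), 2)
    ev = evaluate_clustering(res.scores, 2, seed=0, reference_labels=coh.populations)
    assert -1 <= ev.silhouette <= 1
    assert ev.ari <= 1 and 0 <= ev.nmi <= 1
    assert ev.composition.to_numpy().sum() == 200
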