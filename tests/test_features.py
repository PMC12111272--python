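import numpy as np
import pytest
from scipy import linalg

from spectrastack.errors import DegenerateDataError, ParameterError
from spectrastack.features import (
    ProjectionModel,
    extractor_fit,
    olda_fit,
    pca_fit,
    pca_lda_fit,
    project,
)


def _blobs(rng, n_per=20, d=None, centers=None, sd=0.3):
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    d = centers.shape[1]
    X, y = [], []
    for c, mu in enumerate(centers):
        X.append(mu + sd * rng.normal(size=(n_per, d)))
        y += [c] * n_per
    return np.vstack(X), np.array(y)


class TestPCA:
    def test_rank_one_line(self):
        t = np.linspace(-1, 1, 20)
        X = np.column_stack([t, 2 * t])
        model = pca_fit(X, n_components=1)
        np.testing.assert_allclose(model.explained_variance_ratio, [1.0], atol=1e-12)

    def test_full_rank_ratios_sum_to_one(self, rng):
        X = rng.normal(size=(30, 5))
        model = pca_fit(X, n_components=5)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalues_match_covariance_oracle(self):
        X = np.array([[1, 2, 0], [3, 1, 4], [2, 5, 1], [0, 2, 3]], dtype=float)
        model = pca_fit(X, n_components=3)
        evals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        # singular values of centered X relate to covariance eigenvalues
        _, s, _ = np.linalg.svd(X - X.mean(0), full_matrices=False)
        np.testing.assert_allclose(s**2 / (X.shape[0] - 1), evals, atol=1e-9)
        np.testing.assert_allclose(
            model.explained_variance_ratio, evals / evals.sum(), atol=1e-9
        )

    def test_variance_target_on_low_rank_data(self, rng):
        B = rng.normal(size=(3, 20))
        X = rng.normal(size=(40, 3)) @ B
        model = pca_fit(X, variance_target=0.993)
        assert model.n_components == 3

    def test_over_requested_components(self, rng):
        with pytest.raises(ParameterError):
            pca_fit(rng.normal(size=(5, 3)), n_components=5)

    def test_reconstruction_error_non_increasing_in_q(self, rng):
        X = rng.normal(size=(30, 8)) * np.arange(1, 9)
        errors = []
        for q in range(1, 8):
            m = pca_fit(X, n_components=q)
            Z = project(m, X)
            recon = Z @ m.components.T + m.mean
            errors.append(np.linalg.norm(X - recon))
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))


class TestProject:
    def test_training_mean_maps_to_zero(self, rng):
        X = rng.normal(size=(20, 6))
        model = pca_fit(X, n_components=3)
        np.testing.assert_allclose(project(model, X.mean(0)[None]), 0.0, atol=1e-10)

    def test_deterministic(self, rng):
        X = rng.normal(size=(15, 6))
        model = pca_fit(X, n_components=2)
        np.testing.assert_array_equal(project(model, X), project(model, X))

    def test_dimension_mismatch(self, rng):
        model = pca_fit(rng.normal(size=(10, 6)), n_components=2)
        with pytest.raises(ParameterError):
            project(model, rng.normal(size=(3, 5)))

    def test_olda_orthonormal_columns_preserve_norms(self, rng):
        X, y = _blobs(rng, centers=rng.normal(size=(3, 12)) * 3)
        model = olda_fit(X, y)
        G = model.components
        z = rng.normal(size=(5, G.shape[1]))
        pts = model.mean + z @ G.T
        np.testing.assert_allclose(
            np.linalg.norm(project(model, pts), axis=1),
            np.linalg.norm(z, axis=1),
            atol=1e-8,
        )


class TestPcaLda:
    def test_two_blob_separation(self, rng):
        X, y = _blobs(rng, n_per=30, centers=[np.zeros(10), np.full(10, 3.0)])
        model = pca_lda_fit(X, y, pca_components=5)
        assert model.n_components == 1
        Z = project(model, X)
        m0, m1 = Z[y == 0].mean(), Z[y == 1].mean()
        pooled = np.sqrt(0.5 * (Z[y == 0].var(ddof=1) + Z[y == 1].var(ddof=1)))
        assert abs(m0 - m1) / pooled > 5

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ParameterError):
            pca_lda_fit(X, np.zeros(10, dtype=int))

    def test_composed_map_equals_sequential_stages(self, rng):
        X, y = _blobs(rng, n_per=25, d=12, centers=rng.normal(size=(3, 12)) * 2)
        model = pca_lda_fit(X, y, pca_components=6)
        # oracle: run the two stages separately and compare spans via
        # projections of fresh points
        pca = pca_fit(X, n_components=6)
        Z = project(pca, X)
        Sw, Sb = np.zeros((6, 6)), np.zeros((6, 6))
        mu = Z.mean(0)
        for c in np.unique(y):
            Zc = Z[y == c]
            d_ = Zc - Zc.mean(0)
            Sw += d_.T @ d_
            dm = (Zc.mean(0) - mu)[:, None]
            Sb += Zc.shape[0] * dm @ dm.T
        evals, evecs = linalg.eigh(Sb, Sw)
        W = evecs[:, np.argsort(evals)[::-1][:2]]
        Xnew = rng.normal(size=(7, 12))
        expected = (project(pca, Xnew)) @ W
        got = project(model, Xnew)
        # same subspace up to per-column sign/scale: compare correlations
        for j in range(2):
            corr = np.corrcoef(expected[:, j], got[:, j])[0, 1]
            assert abs(corr) > 1 - 1e-8


class TestOlda:
    def test_orthonormal_on_undersampled_data(self, rng):
        X = rng.normal(size=(30, 100))
        y = np.repeat([0, 1, 2], 10)
        model = olda_fit(X, y)
        G = model.components
        np.testing.assert_allclose(G.T @ G, np.eye(G.shape[1]), atol=1e-8)

    def test_matches_fisher_direction_two_classes(self, rng):
        X, y = _blobs(rng, n_per=50, d=2, centers=[[0, 0], [2, 1]], sd=0.5)
        model = olda_fit(X, y)
        Sw = np.zeros((2, 2))
        for c in (0, 1):
            d_ = X[y == c] - X[y == c].mean(0)
            Sw += d_.T @ d_
        fisher = np.linalg.solve(Sw, X[y == 0].mean(0) - X[y == 1].mean(0))
        g = model.components[:, 0]
        cos = abs(fisher @ g) / (np.linalg.norm(fisher) * np.linalg.norm(g))
        assert cos >= 1 - 1e-8

    def test_five_class_fixture_gives_four_components(self, small_data):
        model = olda_fit(small_data.absorbance, small_data.labels)
        assert model.n_components == 4

    def test_single_class_rejected(self, rng):
        with pytest.raises(ParameterError):
            olda_fit(rng.normal(size=(10, 5)), np.zeros(10, dtype=int))

    def test_equal_class_means_degenerate(self, rng):
        base = rng.normal(size=(10, 5))
        X = np.vstack([base, base])  # identical class clouds => equal means
        y = np.repeat([0, 1], 10)
        with pytest.raises(DegenerateDataError):
            olda_fit(X, y)

    def test_sample_order_invariance_up_to_sign(self, rng):
        X, y = _blobs(rng, n_per=15, d=8, centers=rng.normal(size=(3, 8)) * 2)
        m1 = olda_fit(X, y)
        perm = rng.permutation(len(y))
        m2 = olda_fit(X[perm], y[perm])
        for j in range(m1.n_components):
            dot = abs(m1.components[:, j] @ m2.components[:, j])
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_trace_ratio_matches_generalized_eig_oracle(self, rng):
        # nonsingular regime: projected between/within trace ratio equals the
        # sum of the top C-1 generalized eigenvalues of (Sb, Sw)
        for _ in range(5):
            X, y = _blobs(rng, n_per=30, d=6, centers=rng.normal(size=(3, 6)) * 2)
            model = olda_fit(X, y)
            G = model.components
            Sw, Sb = np.zeros((6, 6)), np.zeros((6, 6))
            mu = X.mean(0)
            for c in np.unique(y):
                Xc = X[y == c]
                d_ = Xc - Xc.mean(0)
                Sw += d_.T @ d_
                dm = (Xc.mean(0) - mu)[:, None]
                Sb += Xc.shape[0] * dm @ dm.T
            got = np.trace(np.linalg.solve(G.T @ Sw @ G, G.T @ Sb @ G))
            evals = np.sort(linalg.eigh(Sb, Sw, eigvals_only=True))[::-1]
            assert got == pytest.approx(evals[:2].sum(), rel=1e-6)


class TestExtractorDispatch:
    def test_unknown_name(self, rng):
        with pytest.raises(ParameterError):
            extractor_fit("plsda", rng.normal(size=(10, 4)))

    def test_irrelevant_keys_warned_and_ignored(self, rng, caplog):
        X, y = _blobs(rng, n_per=10, d=6, centers=rng.normal(size=(2, 6)) * 3)
        with caplog.at_level("WARNING"):
            model = extractor_fit("olda", X, y, config={"pca_components": 5})
        assert any("pca_components" in r.message for r in caplog.records)
        assert model.kind == "olda"

    def test_component_bookkeeping_on_fixture(self, small_data):
        X, y = small_data.absorbance, small_data.labels
        q = {}
        for name in ("pca", "pca+lda", "olda"):
            model = extractor_fit(name, X, y)
            q[name] = project(model, X).shape[1]
        assert q["pca+lda"] == 4 and q["olda"] == 4
        assert 1 <= q["pca"] <= X.shape[0] - 1

    def test_serialization_round_trip(self, rng):
        model = pca_fit(rng.normal(size=(12, 5)), n_components=3)
        clone = ProjectionModel.from_dict(model.to_dict())
        X = rng.normal(size=(4, 5))
        np.testing.assert_allclose(project(model, X), project(clone, X), atol=1e-12)
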