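"""PCA-LDA model: PCA against a dense eigensolver, LDA against closed forms
and scikit-learn, leakage-free LOOCV, apportionment, recovery properties."""

import numpy as np
import pytest

from opticell.classify import (
    FeatureMatrix,
    PcaLda,
    apportion,
    fit_lda,
    fit_pca,
    loocv_accuracy,
)
from opticell.msproc import N_BINS, normalize_and_bin

from conftest import make_class_spectra


def pad_to_bins(X):
    """Embed a small matrix into the 3,000-column feature space."""
    out = np.zeros((X.shape[0], N_BINS))
    out[:, : X.shape[1]] = X
    return out


def binned_matrix(spectra):
    return np.vstack([normalize_and_bin(s).values for s in spectra])


class TestFitPca:
    def test_identical_rows_rejected(self):
        X = np.ones((5, 20))
        with pytest.raises(ValueError, match="variance"):
            fit_pca(X, 2)

    def test_rank_two_data_fully_captured(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 30))
        coeffs = rng.normal(size=(15, 2))
        X = coeffs @ basis + rng.normal(size=30)
        _, _, explained, _ = fit_pca(X, 2)
        assert explained.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_dense_eigendecomposition(self):
        """Loadings and explained fractions agree with a brute-force
        eigendecomposition of the sample covariance within 1e-8."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(20, 50))
        mean, loadings, explained, scores = fit_pca(X, 3)
        cov = np.cov(X, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(3):
            ref = evecs[:, j]
            if ref[np.argmax(np.abs(ref))] < 0:
                ref = -ref
            assert np.allclose(loadings[j], ref, atol=1e-8)
            assert explained[j] == pytest.approx(evals[j] / evals.sum(), abs=1e-8)
        assert np.allclose(scores, (X - mean) @ loadings.T, atol=1e-12)

    def test_loadings_orthonormal_and_fractions_monotone(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(25, 40))
        _, loadings, explained, scores = fit_pca(X, 4)
        assert np.allclose(loadings @ loadings.T, np.eye(4), atol=1e-10)
        assert np.all(np.diff(explained) <= 1e-12)
        assert explained.sum() <= 1.0 + 1e-12
        # score variance never exceeds data variance
        Xc = X - X.mean(axis=0)
        assert scores.var(ddof=1, axis=0).sum() <= (Xc**2).sum() / (len(X) - 1) + 1e-9

    def test_invalid_k_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 10))
        with pytest.raises(ValueError):
            fit_pca(X, 5)  # k > n-1


class TestFitLda:
    def test_1d_midpoint_threshold(self):
        scores = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = ["a", "a", "b", "b"]
        disc = fit_lda(scores, labels)
        assert disc.threshold == pytest.approx(
            5.5 * disc.direction[0] * np.sign(disc.direction[0])
        ) or abs(abs(disc.threshold) - 5.5) < 1e-9
        assert disc.classify(scores) == ["b", "b", "a", "a"] or disc.classify(scores) == ["a", "a", "b", "b"]
        # perfect separation either way round
        assert disc.classify(np.array([[0.5]]))[0] == "a"
        assert disc.classify(np.array([[10.5]]))[0] == "b"

    def test_isotropic_direction_parallel_to_mean_difference(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1.0, size=(50, 2)) + [0, 0]
        b = rng.normal(0, 1.0, size=(50, 2)) + [5, 5]
        disc = fit_lda(np.vstack([a, b]), ["a"] * 50 + ["b"] * 50)
        delta = a.mean(axis=0) - b.mean(axis=0)
        cos = abs(disc.direction @ delta) / np.linalg.norm(delta)
        assert cos == pytest.approx(1.0, abs=0.05)  # near-isotropic sample Sw

    def test_anisotropic_matches_linear_solve_oracle(self):
        rng = np.random.default_rng(2)
        cov = np.array([[4.0, 1.2], [1.2, 0.5]])
        L = np.linalg.cholesky(cov)
        a = rng.normal(size=(200, 2)) @ L.T
        b = rng.normal(size=(200, 2)) @ L.T + [3.0, 1.0]
        labels = ["a"] * 200 + ["b"] * 200
        scores = np.vstack([a, b])
        disc = fit_lda(scores, labels)
        mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
        sw = ((a - mu_a).T @ (a - mu_a) + (b - mu_b).T @ (b - mu_b)) / (400 - 2)
        w_ref = np.linalg.solve(sw, mu_a - mu_b)
        w_ref /= np.linalg.norm(w_ref)
        if mu_a @ w_ref < mu_b @ w_ref:
            w_ref = -w_ref
        assert np.allclose(disc.direction, w_ref, atol=1e-8)

    def test_matches_sklearn_decision_boundary(self):
        """Independent cross-check: predictions agree with scikit-learn's LDA
        (equal priors) on a random 2-D two-class problem."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        a = rng.normal(size=(40, 2))
        b = rng.normal(size=(40, 2)) + [2.5, -1.0]
        X = np.vstack([a, b])
        labels = ["a"] * 40 + ["b"] * 40
        disc = fit_lda(X, labels)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, labels)
        probe = rng.normal(size=(200, 2)) * 2 + [1.2, -0.5]
        ours = disc.classify(probe)
        theirs = list(sk.predict(probe))
        agreement = np.mean([o == t for o, t in zip(ours, theirs)])
        assert agreement >= 0.99

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.array([[0.0], [1.0], [2.0]]), ["a", "a", "b"])


class TestLoocv:
    def test_chance_level_for_random_labels(self):
        """Identically distributed classes with arbitrary labels: LOOCV
        accuracy stays in the chance band [0.25, 0.75] for every seed."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pad_to_bins(rng.normal(size=(40, 30)))
            labels = ["a", "b"] * 20
            result = loocv_accuracy(X, labels, k=2)
            assert 0.25 <= result.accuracy <= 0.75

    def test_separated_clusters_perfect(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, size=(10, 5))
        b = rng.normal(0.0, 1.0, size=(10, 5))
        b[:, 0] += 10.0  # 10-sigma separation dominates fold perturbation
        X = pad_to_bins(np.vstack([a, b]))
        labels = ["a"] * 10 + ["b"] * 10
        assert loocv_accuracy(X, labels, k=2).accuracy == 1.0

    def test_singleton_class_rejected(self):
        X = pad_to_bins(np.random.default_rng(0).normal(size=(4, 5)))
        with pytest.raises(ValueError):
            loocv_accuracy(X, ["a", "a", "a", "b"], k=1)

    def test_invariant_under_row_permutation(self, euglena, phacus):
        X = binned_matrix(
            make_class_spectra(euglena, 8, seed=1) + make_class_spectra(phacus, 8, seed=2)
        )
        labels = ["euglena"] * 8 + ["phacus"] * 8
        base = loocv_accuracy(X, labels, k=2).accuracy
        rng = np.random.default_rng(5)
        perm = rng.permutation(16)
        permuted = loocv_accuracy(X[perm], [labels[i] for i in perm], k=2).accuracy
        assert permuted == base

    def test_invariant_under_global_rescaling(self, euglena, phacus):
        X = binned_matrix(
            make_class_spectra(euglena, 6, seed=3) + make_class_spectra(phacus, 6, seed=4)
        )
        labels = ["euglena"] * 6 + ["phacus"] * 6
        base = loocv_accuracy(X, labels, k=2)
        scaled = loocv_accuracy(X * 37.5, labels, k=2)
        assert scaled.predicted == base.predicted


class TestModelResults:
    def make_results(self, euglena, phacus, n=12):
        X = binned_matrix(
            make_class_spectra(euglena, n, seed=10) + make_class_spectra(phacus, n, seed=11)
        )
        labels = ["euglena"] * n + ["phacus"] * n
        return PcaLda(X, labels=labels).fit(k=2), X, labels

    def test_training_centroid_classified_to_its_class(self, euglena, phacus):
        results, X, labels = self.make_results(euglena, phacus)
        for name in results.discriminant.class_names:
            centroid_scores = results.class_centroids[name]
            row = results.mean + centroid_scores @ results.loadings
            assert results.predict(row[None, :]) == [name]

    def test_empty_test_set(self, euglena, phacus):
        results, _, _ = self.make_results(euglena, phacus)
        res = results.apportion(FeatureMatrix(values=np.empty((0, N_BINS))))
        assert res.predicted == []
        assert res.accuracy is None

    def test_contaminated_phacus_classified_euglena(self, euglena, phacus):
        """An 80:20 Euglena:Phacus mixture recorded as Phacus lands on the
        Euglena side — the co-capture failure mode."""
        from opticell.synthetic import contaminate, generate_spectrum

        results, _, _ = self.make_results(euglena, phacus)
        e = generate_spectrum(euglena, 5e4, 0.0, seed=20)
        p = generate_spectrum(phacus, 5e4, 0.0, seed=21)
        mixed = contaminate(p, e, 0.8)  # 80% Euglena signal
        fm = FeatureMatrix(values=normalize_and_bin(mixed).values[None, :], labels=["phacus"])
        res = apportion(results, fm)
        assert res.predicted == ["euglena"]
        assert res.accuracy == 0.0

    def test_apportion_reproduces_training_scores(self, euglena, phacus):
        """Affine consistency: projecting the training rows reproduces the
        training scores within 1e-10."""
        results, X, labels = self.make_results(euglena, phacus)
        assert np.allclose(results.transform(X), results.training_scores, atol=1e-10)

    def test_column_mismatch_rejected(self, euglena, phacus):
        results, _, _ = self.make_results(euglena, phacus)
        with pytest.raises(ValueError):
            results.transform(np.zeros((1, 100)))

    def test_json_round_trip(self, euglena, phacus, tmp_path):
        results, X, _ = self.make_results(euglena, phacus)
        path = tmp_path / "model.json"
        results.to_json(path)
        from opticell.classify import PcaLdaResults

        loaded = PcaLdaResults.from_json(path)
        assert loaded.predict(X) == results.predict(X)
        assert np.allclose(loaded.mean, results.mean)

    def test_summary_mentions_key_quantities(self, euglena, phacus):
        results, _, _ = self.make_results(euglena, phacus)
        text = results.summary()
        assert "explained variance" in text
        assert "euglena" in text and "phacus" in text

    def test_score_plot_written(self, euglena, phacus, tmp_path):
        results, X, labels = self.make_results(euglena, phacus)
        out = tmp_path / "scores.png"
        results.plot_scores(X_test=FeatureMatrix(values=X), path=out)
        assert out.stat().st_size > 0

    def test_discriminative_bins_recovered(self):
        """The largest-|weight| bins of the pulled-back discriminant include
        the bins that actually differ between classes (hit rate >= 0.8 over
        10 seeds)."""
        hits, total = 0, 0
        informative = [100, 700, 1500, 2400]
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base = rng.uniform(0.5, 1.0, N_BINS) * 0.01
            Xa = np.tile(base, (12, 1)) + rng.normal(0, 1e-3, (12, N_BINS))
            Xb = np.tile(base, (12, 1)) + rng.normal(0, 1e-3, (12, N_BINS))
            Xb[:, informative] += 0.02
            X = np.abs(np.vstack([Xa, Xb]))
            labels = ["a"] * 12 + ["b"] * 12
            results = PcaLda(X, labels=labels).fit(k=2)
            top10 = set(np.argsort(np.abs(results.feature_weights()))[-10:])
            hits += len(top10 & set(informative))
            total += len(informative)
        assert hits / total >= 0.8
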