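import numpy as np
import pytest

from nightcough.gmm import (GMMClassifier, GaussianMixtureModel, fit_gmm,
                            gmm_likelihood, gmm_llr, gmm_log_likelihood,
                            gmm_llr_single, select_orders)


def _mixture_sample(rng, n=2000):
    """Well-separated 2-component diagonal mixture in 3-D."""
    z = rng.random(n) < 0.4
    mu = np.array([[0.0, 0.0, 0.0], [5.0, -4.0, 6.0]])
    sd = np.array([[1.0, 0.5, 0.8], [0.6, 1.2, 0.7]])
    comp = z.astype(int)
    return mu[comp] + sd[comp] * rng.standard_normal((n, 3)), mu


class TestFitGMM:
    def test_order_one_closed_form(self, rng):
        X = rng.standard_normal((500, 4)) * [1, 2, 3, 4] + [0, 1, 2, 3]
        m = fit_gmm(X, 1, rng)
        assert np.allclose(m.means[0], X.mean(axis=0), atol=1e-10)
        assert np.allclose(m.variances[0], X.var(axis=0), atol=1e-8)
        assert np.allclose(m.weights, [1.0])

    def test_two_component_recovery(self, rng):
        X, mu_true = _mixture_sample(rng)
        m = fit_gmm(X, 2, rng)
        # match components to ground truth by nearest mean
        order = np.argsort(m.means[:, 0])
        truth = mu_true[np.argsort(mu_true[:, 0])]
        assert np.all(np.abs(m.means[order] - truth) < 0.1)

    def test_loglik_monotone(self, rng):
        X, _ = _mixture_sample(rng, n=600)
        m = fit_gmm(X, 3, rng, n_restarts=1)
        hist = m.log_likelihood_history
        assert np.all(np.diff(hist) >= -1e-9)

    def test_order_exceeds_rows_errors(self, rng):
        with pytest.raises(ValueError, match="order"):
            fit_gmm(rng.standard_normal((5, 2)), 10, rng)

    def test_variance_floor(self, rng):
        X = np.zeros((50, 2))  # degenerate data would collapse variances
        m = fit_gmm(X, 1, rng)
        assert np.all(m.variances >= 1e-6)


class TestLikelihood:
    def test_density_at_mean_identity_cov(self):
        D = 5
        m = GaussianMixtureModel(weights=np.array([1.0]),
                                 means=np.zeros((1, D)),
                                 variances=np.ones((1, D)))
        val = gmm_likelihood(m, np.zeros(D))
        assert val == pytest.approx((2 * np.pi) ** (-D / 2), rel=1e-12)

    def test_matches_bruteforce_sum(self, rng):
        D, order = 4, 6
        m = GaussianMixtureModel(
            weights=rng.dirichlet(np.ones(order)),
            means=rng.standard_normal((order, D)),
            variances=rng.uniform(0.5, 2.0, (order, D)))
        for _ in range(20):
            b = rng.standard_normal(D)
            brute = 0.0
            for i in range(order):
                det = np.prod(m.variances[i])
                quad = np.sum((b - m.means[i]) ** 2 / m.variances[i])
                brute += m.weights[i] * (2 * np.pi) ** (-D / 2) * \
                    det ** -0.5 * np.exp(-0.5 * quad)
            assert gmm_likelihood(m, b) == pytest.approx(brute, rel=1e-10)

    def test_duplicate_components_convexity(self, rng):
        D = 3
        mu = rng.standard_normal((1, D))
        var = rng.uniform(0.5, 1.5, (1, D))
        single = GaussianMixtureModel(np.array([1.0]), mu, var)
        double = GaussianMixtureModel(np.array([0.5, 0.5]),
                                      np.vstack([mu, mu]), np.vstack([var, var]))
        b = rng.standard_normal(D)
        assert gmm_likelihood(double, b) == pytest.approx(
            gmm_likelihood(single, b), rel=1e-12)

    def test_dimension_mismatch_errors(self, rng):
        m = GaussianMixtureModel(np.array([1.0]), np.zeros((1, 3)),
                                 np.ones((1, 3)))
        with pytest.raises(ValueError, match="dimension"):
            gmm_log_likelihood(m, np.zeros((1, 5)))

    def test_log_vs_linear_agreement(self, rng):
        m = GaussianMixtureModel(
            weights=np.array([0.3, 0.7]),
            means=rng.standard_normal((2, 3)),
            variances=rng.uniform(0.5, 1.5, (2, 3)))
        for _ in range(10):
            b = rng.standard_normal(3)
            log_val = gmm_log_likelihood(m, b[None])[0]
            assert np.log(gmm_likelihood(m, b)) == pytest.approx(
                log_val, abs=1e-8)


def _three_models(rng, D=2):
    def model(center):
        return GaussianMixtureModel(np.array([1.0]),
                                    np.full((1, D), float(center)),
                                    np.ones((1, D)))
    return {"cough": model(0), "snore": model(5), "noise": model(-5)}


class TestLLR:
    def test_zero_when_equal(self, rng):
        models = _three_models(rng)
        # at the midpoint between cough and snore centres, S1 == S2 > S3
        beta = np.full(2, 2.5)
        llr = gmm_llr(models, beta)[0]
        assert llr == pytest.approx(0.0, abs=1e-10)

    def test_log_identity(self):
        # S1 = e * S2, S3 < S2  ->  LLR = 1
        m1 = GaussianMixtureModel(np.array([1.0]), np.zeros((1, 1)),
                                  np.ones((1, 1)))
        s1 = gmm_log_likelihood(m1, np.zeros((1, 1)))[0]
        # construct by shifting the mean so that log-density drops by 1
        m2 = GaussianMixtureModel(np.array([1.0]),
                                  np.full((1, 1), np.sqrt(2.0)),
                                  np.ones((1, 1)))
        s2 = gmm_log_likelihood(m2, np.zeros((1, 1)))[0]
        assert s1 - s2 == pytest.approx(1.0, rel=1e-12)

    def test_sensitivity_monotone_in_threshold(self, rng):
        scores = rng.standard_normal(500)
        labels = rng.random(500) < 0.3
        sens = [np.mean(scores[labels] > th) for th in np.linspace(-3, 3, 50)]
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_llr_single_reports_class_scores(self, rng):
        models = _three_models(rng)
        res = gmm_llr_single(models, np.zeros(2))
        assert set(res.class_scores if hasattr(res, "class_scores")
                   else res.class_log_scores) == {"cough", "snore", "noise"}
        assert res.value > 0   # at the cough centre


class TestClassifier:
    @staticmethod
    def _toy_data(rng, n=300):
        X = np.vstack([
            rng.standard_normal((n, 3)) + [0, 0, 0],
            rng.standard_normal((n, 3)) + [6, 0, 0],
            rng.standard_normal((n, 3)) + [0, 6, 0]])
        y = np.array(["cough"] * n + ["snore"] * n + ["noise"] * n)
        return X, y

    def test_fit_predict_separable(self, rng):
        X, y = self._toy_data(rng)
        clf = GMMClassifier.fit(X, y, orders=(1, 1, 1), rng=0, threshold=0.0)
        pred = clf.predict(X)
        acc = np.mean((pred == "cough") == (y == "cough"))
        assert acc > 0.95

    def test_save_load_roundtrip(self, rng, tmp_path):
        X, y = self._toy_data(rng, n=100)
        clf = GMMClassifier.fit(X, y, orders=(1, 1, 2), rng=0)
        clf.save(tmp_path / "m.json")
        clf2 = GMMClassifier.load(tmp_path / "m.json")
        assert np.allclose(clf.llr(X), clf2.llr(X))

    def test_missing_class_errors(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.array(["cough"] * 10)
        with pytest.raises(ValueError, match="snore"):
            GMMClassifier.fit(X, y)


class TestSelectOrders:
    @staticmethod
    def _blob_data(rng, noise_blobs=1, n=120):
        parts, labels = [], []
        parts.append(rng.standard_normal((n, 2)) * 0.5 + [0, 8])
        labels += ["cough"] * n
        parts.append(rng.standard_normal((n, 2)) * 0.5 + [8, 0])
        labels += ["snore"] * n
        # one noise blob adjacent to the cough blob so a low-order noise
        # model leaks false positives and selection must raise the order
        centers = [[0, 6], [-8, 8], [8, 8], [-8, -8]][:noise_blobs]
        for c in centers:
            parts.append(rng.standard_normal((n // noise_blobs, 2)) * 0.5 + c)
            labels += ["noise"] * (n // noise_blobs)
        X = np.vstack(parts)
        return X, np.array(labels)

    def test_single_blobs_select_one(self, rng):
        X, y = self._blob_data(rng, noise_blobs=1)
        Xd, yd = self._blob_data(np.random.default_rng(1), noise_blobs=1)
        orders = select_orders(X, y, Xd, yd, max_order=3)
        assert orders == (1, 1, 1)

    def test_multi_blob_noise_needs_higher_order(self, rng):
        X, y = self._blob_data(rng, noise_blobs=4, n=240)
        Xd, yd = self._blob_data(np.random.default_rng(1), noise_blobs=4, n=240)
        orders = select_orders(X, y, Xd, yd, max_order=6)
        assert orders[2] >= 4
        assert all(o <= 6 for o in orders)

    def test_orders_capped(self, rng):
        X, y = self._blob_data(rng)
        Xd, yd = self._blob_data(np.random.default_rng(1))
        orders = select_orders(X, y, Xd, yd, max_order=2)
        assert all(1 <= o <= 2 for o in orders)
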