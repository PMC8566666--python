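import numpy as np
import pytest

from fgdn import (
    ConnectivityMatrix,
    assemble_graphs,
    build_template,
    cheb_conv,
    classify,
    fgdn_forward,
    fgdn_loss,
    init_params,
    normalized_laplacian,
)
from fgdn.chebnet import backward_batch, forward_batch


def random_knn_weights(n, k, rng):
    t = build_template(rng.standard_normal((n, n)), k, "ASD")
    return t.weights


def spectral_filter_oracle(x, lap_pair, theta):
    """Dense spectral-domain filtering U (sum_k theta_k T_k(Lambda~)) U^T X."""
    lam, u = np.linalg.eigh(lap_pair.laplacian)
    lam_t = 2.0 * lam / lap_pair.lambda_max - 1.0
    order = theta.shape[0]
    t_prev, t_cur = np.ones_like(lam_t), lam_t
    polys = [t_prev, t_cur]
    for _ in range(2, order):
        t_prev, t_cur = t_cur, 2.0 * lam_t * t_cur - t_prev
        polys.append(t_cur)
    out = np.zeros((x.shape[0], theta.shape[2]))
    for k in range(order):
        filt = u @ np.diag(polys[k]) @ u.T
        out += filt @ x @ theta[k]
    return out


class TestNormalizedLaplacian:
    def test_two_node_closed_form(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        pair = normalized_laplacian(w)
        np.testing.assert_allclose(pair.laplacian, [[1.0, -1.0], [-1.0, 1.0]], atol=1e-12)
        assert pair.lambda_max == pytest.approx(2.0)
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvalsh(pair.laplacian)), [0.0, 2.0], atol=1e-12
        )

    def test_empty_graph_is_identity(self):
        pair = normalized_laplacian(np.zeros((3, 3)))
        np.testing.assert_array_equal(pair.laplacian, np.eye(3))
        assert pair.lambda_max == pytest.approx(1.0)

    def test_spectrum_bounds_and_null_vector(self, rng):
        w = random_knn_weights(10, 3, rng)
        pair = normalized_laplacian(w)
        eig = np.linalg.eigvalsh(pair.laplacian)
        assert eig.min() >= -1e-9 and eig.max() <= 2 + 1e-9
        eig_t = np.linalg.eigvalsh(pair.rescaled)
        assert eig_t.min() >= -1 - 1e-9 and eig_t.max() <= 1 + 1e-9
        # D^{1/2} 1 spans the 0-eigenspace
        v = np.sqrt(w.sum(axis=1))
        np.testing.assert_allclose(pair.laplacian @ v, 0.0, atol=1e-9)

    def test_asymmetric_rejected(self):
        w = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            normalized_laplacian(w)


class TestChebConv:
    def test_order_one_ignores_graph(self, rng):
        w = random_knn_weights(6, 2, rng)
        pair = normalized_laplacian(w)
        x = rng.standard_normal((6, 4))
        theta = rng.standard_normal((1, 4, 3))
        np.testing.assert_allclose(cheb_conv(x, pair.rescaled, theta), x @ theta[0],
                                   atol=1e-12)

    def test_scalar_chebyshev_recursion(self):
        # T_2(0.5) = 2*0.5*0.5 - 1 = -0.5, realized on a 1-node graph where
        # the rescaled Laplacian is the scalar 0.5
        lt = np.array([[0.5]])
        theta = np.zeros((3, 1, 1))
        theta[2, 0, 0] = 1.0
        out = cheb_conv(np.array([[1.0]]), lt, theta)
        assert out[0, 0] == pytest.approx(-0.5)

    @pytest.mark.parametrize("order", [1, 2, 3, 4, 5])
    def test_matches_spectral_oracle(self, rng, order):
        w = random_knn_weights(6, 2, rng)
        pair = normalized_laplacian(w)
        x = rng.standard_normal((6, 4))
        theta = rng.standard_normal((order, 4, 3))
        got = cheb_conv(x, pair.rescaled, theta)
        want = spectral_filter_oracle(x, pair, theta)
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_k_locality_on_path_graph(self):
        # on a path graph, a K-order filter sees at most K-1 hops
        n, order = 9, 3
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 1.0
        pair = normalized_laplacian(w)
        theta = np.random.default_rng(0).standard_normal((order, 1, 1))
        x = np.zeros((n, 1))
        base = cheb_conv(x, pair.rescaled, theta)
        x2 = x.copy()
        x2[0, 0] = 1.0  # perturb node 0
        delta = cheb_conv(x2, pair.rescaled, theta) - base
        reach = np.flatnonzero(np.abs(delta[:, 0]) > 1e-12)
        assert reach.max() <= order - 1

    def test_dimension_mismatch_fatal(self, rng):
        pair = normalized_laplacian(random_knn_weights(5, 2, rng))
        with pytest.raises(ValueError):
            cheb_conv(rng.standard_normal((5, 3)), pair.rescaled,
                      rng.standard_normal((2, 4, 2)))


class TestForwardAndDecision:
    def _graphs(self, rng, n=6):
        asd_t = build_template(rng.standard_normal((n, n)), 2, "ASD")
        hc_t = build_template(rng.standard_normal((n, n)), 2, "HC")
        m = rng.standard_normal((n, n))
        fc = ConnectivityMatrix("s", "tangent", 0.5 * (m + m.T))
        return assemble_graphs(fc, asd_t, hc_t)

    def test_outputs_are_probabilities(self, rng):
        g_asd, g_hc = self._graphs(rng)
        params = init_params(6, rng, channels=4, hidden=5)
        p_asd, p_hc = fgdn_forward(g_asd, g_hc, params)
        assert 0.0 < p_asd < 1.0 and 0.0 < p_hc < 1.0

    def test_identical_templates_one_pass(self, rng):
        n = 6
        asd_t = build_template(rng.standard_normal((n, n)), 2, "ASD")
        m = rng.standard_normal((n, n))
        fc = ConnectivityMatrix("s", "tangent", 0.5 * (m + m.T))
        g1, g2 = assemble_graphs(fc, asd_t, asd_t)
        params = init_params(n, rng, channels=4, hidden=5)
        p_asd, p_hc = fgdn_forward(g1, g2, params)
        lt = normalized_laplacian(asd_t.weights).rescaled
        pa, ph, _ = forward_batch(fc.values[None], lt, lt, params)
        assert p_asd == pytest.approx(pa[0], abs=1e-12)
        assert p_hc == pytest.approx(ph[0], abs=1e-12)

    def test_inference_deterministic(self, rng):
        g_asd, g_hc = self._graphs(rng)
        params = init_params(6, rng, channels=4, hidden=5)
        out1 = fgdn_forward(g_asd, g_hc, params, dropout=0.1, training=False)
        out2 = fgdn_forward(g_asd, g_hc, params, dropout=0.1, training=False)
        assert out1 == out2

    @pytest.mark.parametrize(
        "p_asd,p_hc,expected",
        [(0.7, 0.3, "ASD"), (0.3, 0.7, "HC"), (0.5, 0.5, "HC")],
    )
    def test_decision_rule(self, p_asd, p_hc, expected):
        assert classify(p_asd, p_hc) == expected


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        loss = fgdn_loss([(1.0 - 1e-7, 1e-7)], ["ASD"])
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_uniform_prediction_analytic(self):
        assert fgdn_loss([(0.5, 0.5)], ["ASD"]) == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_batch_additivity(self, rng):
        preds = [tuple(rng.uniform(0.1, 0.9, 2)) for _ in range(6)]
        labels = ["ASD", "HC"] * 3
        total = fgdn_loss(preds, labels)
        parts = sum(fgdn_loss([p], [lab]) for p, lab in zip(preds, labels))
        assert total == pytest.approx(parts, abs=1e-10)

    def test_nonnegative_and_zero_only_when_confident(self, rng):
        for _ in range(20):
            p = tuple(rng.uniform(1e-6, 1 - 1e-6, 2))
            loss = fgdn_loss([p], ["ASD"])
            assert loss >= 0.0
            if loss < 1e-5:
                assert p[0] > 0.999 and p[1] < 0.001

    def test_empty_batch_fatal(self):
        with pytest.raises(ValueError):
            fgdn_loss([], [])


class TestGradients:
    def test_analytic_matches_central_differences(self, rng):
        """Backprop through both shared-weight passes vs finite differences."""
        n, order, channels, hidden, batch = 6, 3, 4, 5, 3
        lt_a = normalized_laplacian(random_knn_weights(n, 2, rng)).rescaled
        lt_h = normalized_laplacian(random_knn_weights(n, 2, rng)).rescaled
        x = rng.standard_normal((batch, n, n))
        y = np.array([1.0, 0.0, 1.0])
        params = init_params(n, rng, order=order, channels=channels, hidden=hidden)

        def loss_fn():
            pa, ph, _ = forward_batch(x, lt_a, lt_h, params)
            pa = np.clip(pa, 1e-12, 1 - 1e-12)
            ph = np.clip(ph, 1e-12, 1 - 1e-12)
            return float(
                -(y * np.log(pa) + (1 - y) * np.log(1 - pa)).sum()
                - ((1 - y) * np.log(ph) + y * np.log(1 - ph)).sum()
            )

        _, _, caches = forward_batch(x, lt_a, lt_h, params)
        grads = backward_batch(caches, params, y)

        eps = 1e-6
        tensors = params.as_dict()
        for name, tensor in tensors.items():
            flat = tensor.reshape(-1)
            g_flat = np.asarray(grads[name]).reshape(-1)
            idx = range(flat.size) if flat.size <= 40 else \
                rng.choice(flat.size, 40, replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_fn()
                flat[i] = orig - eps
                down = loss_fn()
                flat[i] = orig
                fd = (up - down) / (2 * eps)
                denom = max(abs(fd), abs(g_flat[i]), 1e-8)
                assert abs(fd - g_flat[i]) / denom < 1e-5, (
                    f"{name}[{i}]: analytic {g_flat[i]:.8g} vs fd {fd:.8g}"
                )
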