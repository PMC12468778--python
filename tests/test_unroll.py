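import numpy as np
import pytest

import demun
from demun import (
    ConfigurationError,
    IterateState,
    MemoryCoefficients,
    ProjectorConfig,
    UnrolledNetwork,
    amp_recover,
    demun_step,
    forward,
    make_gaussian_model,
    mc_divergence,
    nesterov_gammas,
    pgd_step,
    run_unrolled,
    soft_threshold,
)

IDENT = lambda x: x  # noqa: E731


def _instance(side=6, rate=0.5, seed=0, noiseless=True):
    rng = np.random.default_rng(seed)
    model = make_gaussian_model(side, rate, seed=seed + 1000)
    x_true = rng.random((side, side))
    y = forward(model, x_true)
    return model, x_true, y


class TestMemoryCoefficients:
    def test_triangular_storage_counts(self):
        c = MemoryCoefficients.pgd_view(6, 0.5)
        assert [b.size for b in c.betas] == [1, 2, 3, 4, 5, 6]
        assert c.n_beta == 6 * 7 // 2

    def test_malformed_rows_rejected(self):
        with pytest.raises(ConfigurationError):
            MemoryCoefficients(alphas=np.ones(2), betas=[np.zeros(1), np.zeros(3)])


class TestPGD:
    def test_fixed_point_at_truth(self):
        model, x_true, y = _instance()
        state = IterateState(y=y, x=x_true)
        assert np.abs(pgd_step(state, model, 0.7) - x_true).max() < 1e-12

    def test_mu_zero_keeps_iterate(self, rng):
        model, _, y = _instance()
        x = rng.random((6, 6))
        assert np.array_equal(pgd_step(IterateState(y=y, x=x), model, 0.0), x)

    def test_matches_dense_closed_form_recursion(self):
        # identity projector, noiseless, mu = 1/sigma_max^2: every iterate
        # equals the explicit dense recursion x_{k+1} = x_k + mu A^T(y - A x_k)
        model, x_true, y = _instance(side=6, rate=0.5, seed=2)
        A = model.matrix
        mu = 1.0 / np.linalg.svd(A, compute_uv=False)[0] ** 2
        trace = run_unrolled("pgd", IDENT, model, y, T=50, mu=mu)
        xk = np.zeros(36)
        for i in range(50):
            xk = xk + mu * A.T @ (y - A @ xk)
            assert np.abs(trace.xs[i].ravel() - xk).max() < 1e-8

    def test_error_to_least_squares_non_increasing(self):
        model, x_true, y = _instance(side=6, rate=0.5, seed=5)
        A = model.matrix
        mu = 1.0 / np.linalg.svd(A, compute_uv=False)[0] ** 2
        x_ls = np.linalg.lstsq(A, y, rcond=None)[0]
        trace = run_unrolled("pgd", IDENT, model, y, T=40, mu=mu)
        errs = [np.linalg.norm(x.ravel() - x_ls) for x in trace.xs]
        assert all(e1 <= e0 + 1e-12 for e0, e1 in zip(errs, errs[1:]))


class TestDeMUN:
    def test_pgd_view_reproduces_pgd_exactly(self):
        for seed in range(20):
            model, _, y = _instance(seed=seed)
            mu = 0.5 / model.spectral_norm_sq()
            tr_pgd = run_unrolled("pgd", IDENT, model, y, T=6, mu=mu)
            tr_dm = run_unrolled("demun", IDENT, model, y, T=6,
                                 coeffs=MemoryCoefficients.pgd_view(6, mu))
            for a, b in zip(tr_pgd.xs, tr_dm.xs):
                assert np.abs(a - b).max() <= 1e-9

    def test_first_step_is_scaled_backprojection(self):
        model, _, y = _instance()
        coeffs = MemoryCoefficients(alphas=[2.0], betas=[[0.3]])
        tr = run_unrolled("demun", IDENT, model, y, T=1, coeffs=coeffs)
        assert np.abs(tr.xs[0] - 0.3 * demun.adjoint(model, y)).max() < 1e-12

    def test_conv1x1_path_equals_termwise_sum(self, rng):
        model, _, y = _instance(seed=7)
        T = 6
        coeffs = MemoryCoefficients(
            alphas=rng.standard_normal(T),
            betas=[rng.standard_normal(i + 1) * 0.1 for i in range(T)],
        )
        tr_a = run_unrolled("demun", IDENT, model, y, T=T, coeffs=coeffs,
                            demun_via="conv1x1")
        tr_b = run_unrolled("demun", IDENT, model, y, T=T, coeffs=coeffs,
                            demun_via="sum")
        for a, b in zip(tr_a.xs, tr_b.xs):
            assert np.abs(a - b).max() < 1e-9

    def test_incomplete_history_rejected(self):
        model, _, y = _instance()
        state = IterateState(y=y, x=np.zeros((6, 6)), i=1, grads=[np.zeros((6, 6))])
        with pytest.raises(ConfigurationError):
            demun_step(state, MemoryCoefficients.pgd_view(3, 1.0))


class TestNesterov:
    def test_gamma_zero_reduces_to_pgd(self):
        model, _, y = _instance()
        x = np.random.default_rng(0).random((6, 6))
        state = IterateState(y=y, x=x, x_prev=np.zeros((6, 6)))
        a = demun.nesterov_step(state, model, 0.3, gamma=0.0)
        b = pgd_step(state, model, 0.3)
        assert np.abs(a - b).max() < 1e-12

    def test_matches_textbook_recursion(self):
        # independent reference implementation of the accelerated scheme
        model, _, y = _instance(seed=11)
        A = model.matrix
        mu = 1.0 / np.linalg.svd(A, compute_uv=False)[0] ** 2
        T = 25
        trace = run_unrolled("nesterov", IDENT, model, y, T=T, mu=mu)
        x, x_prev, t = np.zeros(36), np.zeros(36), 1.0
        for i in range(T):
            t_next = (1 + np.sqrt(1 + 4 * t * t)) / 2
            z = x + (t - 1) / t_next * (x - x_prev)
            x_new = z + mu * A.T @ (y - A @ z)
            x_prev, x, t = x, x_new, t_next
            assert np.abs(trace.xs[i].ravel() - x).max() < 1e-10

    def test_memory_coefficients_reproduce_nesterov(self):
        # with an identity projector the first iterates are linear in the
        # stored gradients, so a small least-squares solve recovers exact
        # memory coefficients reproducing the accelerated trace
        model, _, y = _instance(seed=13)
        mu = 0.8 / model.spectral_norm_sq()
        T = 3
        tr_nest = run_unrolled("nesterov", IDENT, model, y, T=T, mu=mu)
        xs = [np.zeros((6, 6))] + list(tr_nest.xs)
        grads = [demun.adjoint(model, y - forward(model, x)) for x in xs[:T]]
        alphas, betas = [], []
        for i in range(T):
            cols = [xs[i].ravel()] + [g.ravel() for g in grads[: i + 1]]
            M = np.stack(cols, axis=1)
            coef, res, *_ = np.linalg.lstsq(M, xs[i + 1].ravel(), rcond=None)
            assert np.abs(M @ coef - xs[i + 1].ravel()).max() < 1e-9
            alphas.append(coef[0])
            betas.append(coef[1:])
        tr_dm = run_unrolled("demun", IDENT, model, y, T=T,
                             coeffs=MemoryCoefficients(alphas=alphas, betas=betas))
        for a, b in zip(tr_nest.xs, tr_dm.xs):
            assert np.abs(a - b).max() < 1e-8

    def test_gamma_schedule_values(self):
        g = nesterov_gammas(4)
        assert g[0] == 0.0
        assert np.all(g[1:] > 0) and np.all(g < 1)


class TestAMP:
    def test_onsager_off_is_gradient_step_with_unit_mu(self):
        model, _, y = _instance()
        x = np.random.default_rng(1).random((6, 6))
        state = IterateState(y=y, x=x)
        xt, _ = demun.amp_step(state, model, onsager=False)
        ref = pgd_step(state, model, 1.0)
        assert np.abs(xt - ref).max() < 1e-12

    def test_sparse_recovery_reaches_minus_30_db(self):
        # n=256, m=128, 10-sparse signal, soft-threshold denoiser
        rng = np.random.default_rng(42)
        model = make_gaussian_model(16, 0.5, seed=21)
        x_true = np.zeros(256)
        support = rng.choice(256, 10, replace=False)
        x_true[support] = rng.standard_normal(10)
        x_img = x_true.reshape(16, 16)
        y = forward(model, x_img)
        den = lambda v, s: soft_threshold(v, 1.8 * s)  # noqa: E731
        x_hat = amp_recover(model, y, den, iters=30, seed=1)
        nmse = 10 * np.log10(np.sum((x_hat - x_img) ** 2) / np.sum(x_img**2))
        assert nmse < -30

    def test_mc_divergence_matches_linear_closed_form(self):
        # f(v) = c v has divergence c*n exactly; Onsager factor c*n/m
        c = 0.7
        side, rate = 50, 0.4
        model = make_gaussian_model(side, rate, seed=3)
        v = np.random.default_rng(5).standard_normal((side, side))
        est = mc_divergence(lambda u: c * u, v, seed=8, probes=10)
        true = c * side * side
        assert abs(est / true - 1) < 0.02
        assert abs(est / model.m - c * side * side / model.m) / (true / model.m) < 0.02

    def test_warns_for_non_gaussian_matrix(self):
        model = demun.make_dct_model(6, 0.5, seed=0)
        state = IterateState(y=np.zeros(model.m), x=np.zeros((6, 6)))
        with pytest.warns(UserWarning):
            demun.amp_step(state, model)


class TestRunUnrolled:
    def test_t1_zero_projector_demun_is_scaled_backprojection(self):
        model, _, y = _instance()
        zero = lambda x: np.zeros_like(x)  # noqa: E731
        coeffs = MemoryCoefficients(alphas=[1.0], betas=[[0.4]])
        tr = run_unrolled("demun", zero, model, y, T=1, coeffs=coeffs, residual=True)
        assert np.abs(tr.xs[0] - 0.4 * demun.adjoint(model, y)).max() < 1e-12

    @pytest.mark.parametrize("T", [5, 15, 30])
    def test_trace_length_matches_steps(self, T):
        model, _, y = _instance()
        tr = run_unrolled("pgd", IDENT, model, y, T=T, mu=0.01)
        assert len(tr) == T

    def test_invalid_t_rejected(self):
        model, _, y = _instance()
        with pytest.raises(ConfigurationError):
            run_unrolled("pgd", IDENT, model, y, T=0, mu=0.1)

    def test_noiseless_fixed_point_for_all_schemes(self):
        # if x_i = x* and the projector is the identity at x*, the estimate
        # stays at x*; realized by starting DeMUN at beta taking one exact step
        model, x_true, y = _instance()
        state = IterateState(y=y, x=x_true.copy(), x_prev=x_true.copy())
        for step in (lambda: pgd_step(state, model, 0.5),
                     lambda: demun.nesterov_step(state, model, 0.5, 0.6)):
            assert np.abs(step() - x_true).max() < 1e-10


class TestTrainableNetwork:
    def test_trace_determinism(self):
        model, _, y = _instance()
        cfg = ProjectorConfig(L=1, width=4, final_zero_init=False)
        net_a = UnrolledNetwork(model, 3, cfg, scheme="demun", seed=4)
        net_b = UnrolledNetwork(model, 3, cfg, scheme="demun", seed=4)
        tr_a = net_a.reconstruct(y)
        tr_b = net_b.reconstruct(y)
        for a, b in zip(tr_a.xs, tr_b.xs):
            assert np.array_equal(a, b)

    def test_demun_init_matches_pgd_network(self):
        # at initialization (PGD-view coefficients, zero-init output layer,
        # residual projections) the demun and pgd networks produce the same trace
        model, _, y = _instance()
        cfg = ProjectorConfig(L=1, width=4, residual=True)
        net_dm = UnrolledNetwork(model, 4, cfg, scheme="demun", seed=4)
        net_pgd = UnrolledNetwork(model, 4, cfg, scheme="pgd", seed=4)
        tr_a, tr_b = net_dm.reconstruct(y), net_pgd.reconstruct(y)
        for a, b in zip(tr_a.xs, tr_b.xs):
            assert np.abs(a - b).max() < 1e-12

    def test_coefficients_roundtrip(self):
        model, _, y = _instance()
        net = UnrolledNetwork(model, 3, ProjectorConfig(L=0, width=2), scheme="demun")
        c = net.coefficients()
        assert c.T == 3 and np.allclose(c.alphas, 1.0)
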