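"""Training loop: splits, objective, gradients, line search, descent."""

import numpy as np
import pytest

from ecgipoly import (
    PolyNet,
    SimConfig,
    TrainConfig,
    generate_paired_dataset,
    init_linear,
    line_search_update,
    mean_relative_error,
    objective,
    parameter_gradient,
    predict,
    split_time_samples,
    train,
)
from ecgipoly.training import Gradients


class TestSplitTimeSamples:
    def test_partition(self):
        tr, te = split_time_samples(10, 0.5, seed=0)
        assert len(tr) == 5 and len(te) == 5
        assert sorted(np.concatenate([tr, te]).tolist()) == list(range(10))

    def test_deterministic_and_seed_sensitive(self):
        assert np.array_equal(split_time_samples(100, 0.7, 1)[0],
                              split_time_samples(100, 0.7, 1)[0])
        assert not np.array_equal(split_time_samples(100, 0.7, 1)[0],
                                  split_time_samples(100, 0.7, 2)[0])

    def test_clinical_split_size(self):
        # round(0.7 * 15062) = 10543
        tr, _ = split_time_samples(15062, 0.7, seed=0)
        assert len(tr) == 10543

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_time_samples(3, 0.01, seed=0)


class TestObjective:
    def test_zero_at_exact_linear_fit(self, small_dataset):
        u_torso, u_endo, forward = small_dataset
        m_star = u_endo.values @ np.linalg.pinv(u_torso.values)
        net = init_linear(m_star, 3)
        cfg = TrainConfig(lambda_sobolev=0.0)
        idx = np.arange(u_torso.n_samples)
        assert objective(net, u_torso, u_endo, cfg, idx) == pytest.approx(0.0, abs=1e-18)

    def test_lambda_zero_matches_loop_mse(self, rng):
        net = PolyNet(rng.normal(size=(3, 4)), rng.normal(size=(3, 3)))
        ut, ua = rng.normal(size=(4, 12)), rng.normal(size=(3, 12))
        idx = np.array([0, 3, 5, 7])
        cfg = TrainConfig(lambda_sobolev=0.0)
        value = objective(net, ut, ua, cfg, idx)
        total = 0.0
        for t in idx:
            pred = predict(net, _single(ut[:, t])).values[:, 0]
            total += sum((pred[i] - ua[i, t]) ** 2 for i in range(3))
        assert value == pytest.approx(total / len(idx), rel=1e-12)

    def test_sobolev_term_closed_form_at_linear_init(self, rng):
        m0 = rng.normal(size=(4, 3))
        net = init_linear(m0, 3)
        ut, ua = rng.normal(size=(3, 9)), rng.normal(size=(4, 9))
        idx = np.arange(9)
        lam, s = 0.37, 2.0
        cfg_reg = TrainConfig(lambda_sobolev=lam, sobolev_exponent=s, lambda_relative=False)
        cfg_plain = TrainConfig(lambda_sobolev=0.0)
        penalty = objective(net, ut, ua, cfg_reg, idx) - objective(net, ut, ua, cfg_plain, idx)
        assert penalty == pytest.approx(lam * np.sum(np.abs(m0) ** s), rel=1e-10)


def _single(column):
    from ecgipoly import PotentialRecording

    return PotentialRecording(column[:, None], 100.0, tuple(f"c{i}" for i in range(len(column))))


class TestParameterGradient:
    @pytest.mark.parametrize("lam,s", [(0.0, 2.0), (1e-3, 2.0), (1e-3, 1.5)])
    def test_matches_central_differences(self, lam, s, rng):
        net = PolyNet(rng.normal(size=(3, 4)), 0.5 * rng.normal(size=(4, 3)))
        ut, ua = rng.normal(size=(4, 5)), rng.normal(size=(3, 5))
        idx = np.arange(5)
        cfg = TrainConfig(lambda_sobolev=lam, sobolev_exponent=s, lambda_relative=False)
        grads = parameter_gradient(net, ut, ua, cfg, idx)
        h = 1e-6

        def obj(netx):
            return objective(netx, ut, ua, cfg, idx)

        fd_m = np.zeros_like(net.matrix)
        for i in range(3):
            for j in range(4):
                up, dn = net.matrix.copy(), net.matrix.copy()
                up[i, j] += h
                dn[i, j] -= h
                fd_m[i, j] = (obj(PolyNet(up, net.weights)) - obj(PolyNet(dn, net.weights))) / (2 * h)
        assert np.abs(fd_m - grads.matrix).max() / np.abs(fd_m).max() < 1e-5
        fd_w = np.zeros_like(net.weights)
        for k in range(4):
            for i in range(3):
                up, dn = net.weights.copy(), net.weights.copy()
                up[k, i] += h
                dn[k, i] -= h
                fd_w[k, i] = (obj(PolyNet(net.matrix, up)) - obj(PolyNet(net.matrix, dn))) / (2 * h)
        assert np.abs(fd_w - grads.weights).max() / np.abs(fd_w).max() < 1e-5

    def test_stationary_at_exact_solution(self, small_dataset):
        u_torso, u_endo, _ = small_dataset
        m_star = u_endo.values @ np.linalg.pinv(u_torso.values)
        net = init_linear(m_star, 1)
        cfg = TrainConfig(lambda_sobolev=0.0, optimize_weights=False)
        grads = parameter_gradient(net, u_torso, u_endo, cfg, np.arange(u_torso.n_samples))
        assert np.abs(grads.matrix).max() < 1e-10

    def test_residual_linearity(self, rng):
        net = init_linear(rng.normal(size=(3, 4)), 2)
        ut = rng.normal(size=(4, 6))
        ua_zero = np.zeros((3, 6))
        cfg = TrainConfig(lambda_sobolev=0.0)
        idx = np.arange(6)
        g1 = parameter_gradient(net, ut, ua_zero, cfg, idx)
        doubled = PolyNet(2.0 * net.matrix, net.weights)
        g2 = parameter_gradient(doubled, ut, ua_zero, cfg, idx)
        assert np.allclose(g2.matrix, 2.0 * g1.matrix)

    def test_null_gradient_flagged(self):
        g = Gradients(matrix=np.zeros((2, 2)), weights=None)
        assert g.is_null
        with pytest.raises(ValueError, match="zero"):
            g.normalized()


class TestLineSearch:
    def test_returns_unchanged_when_no_trial_improves(self, small_dataset):
        u_torso, u_endo, _ = small_dataset
        m_star = u_endo.values @ np.linalg.pinv(u_torso.values)
        net = init_linear(m_star, 1)
        cfg = TrainConfig(lambda_sobolev=0.0, optimize_weights=False)
        idx = np.arange(u_torso.n_samples)
        direction = Gradients(matrix=np.ones_like(net.matrix), weights=None)
        _, gamma, _ = line_search_update(net, direction, cfg, u_torso, u_endo, idx)
        assert gamma == 0.0

    def test_quadratic_picks_nearest_trial_to_minimizer(self):
        # 1-D quadratic in the single matrix entry: E(m) = (m u - a)^2 summed
        # over one sample with u = 1, a = 0.6, start m = 0; optimal step 0.6,
        # direction +1, trials {-1,-0.5,0,0.5,1} -> expects gamma = 0.5.
        net = init_linear(np.zeros((1, 1)), 1)
        ut = np.array([[1.0]])
        ua = np.array([[0.6]])
        cfg = TrainConfig(lambda_sobolev=0.0, optimize_weights=False,
                          trial_steps=(-1.0, -0.5, 0.0, 0.5, 1.0))
        direction = Gradients(matrix=np.array([[1.0]]), weights=None)
        _, gamma, _ = line_search_update(net, direction, cfg, ut, ua, np.array([0]))
        assert gamma == 0.5

    def test_trial_set_must_contain_zero(self):
        with pytest.raises(ValueError, match="contain 0"):
            TrainConfig(trial_steps=(-1.0, 1.0))


class TestTrain:
    def test_already_optimal_stays_optimal(self, small_dataset):
        u_torso, u_endo, _ = small_dataset
        m_star = u_endo.values @ np.linalg.pinv(u_torso.values)
        net = init_linear(m_star, 3)
        cfg = TrainConfig(lambda_sobolev=0.0, n_iterations=5, seed=3)
        fitted, history = train(net, u_torso, u_endo, cfg)
        assert history.objectives[-1] == pytest.approx(0.0, abs=1e-15)

    def test_monotone_descent_from_perturbed_start(self, small_dataset, rng):
        u_torso, u_endo, _ = small_dataset
        m_star = u_endo.values @ np.linalg.pinv(u_torso.values)
        net = init_linear(m_star * (1 + 0.1 * rng.standard_normal(m_star.shape)), 3)
        cfg = TrainConfig(n_iterations=50, seed=3)
        _, history = train(net, u_torso, u_endo, cfg)
        objectives = np.asarray(history.objectives)
        assert np.all(np.diff(objectives) <= 0.0)
        assert objectives[-1] < objectives[0]

    def test_recovery_on_well_conditioned_linear_data(self):
        """10%-perturbed exact linear inverse retrains to < 1% relative error."""
        cfg = SimConfig(n_torso_leads=12, n_endo_leads=8, duration=2.0,
                        sampling_rate=200.0, noise_sd=0.0, nonlinearity_gain=0.0,
                        n_harmonics=1, drift_amplitude=0.0,
                        subtract_reference=False, seed=21)
        u_torso, u_endo, _ = generate_paired_dataset(cfg)
        tcfg = TrainConfig(lambda_sobolev=0.0, n_iterations=300,
                           train_fraction=0.7, seed=4, optimize_weights=False)
        tr, _ = split_time_samples(u_torso.n_samples, 0.7, tcfg.seed)
        m_star = u_endo.values[:, tr] @ np.linalg.pinv(u_torso.values[:, tr])
        rng = np.random.default_rng(8)
        net = init_linear(m_star * (1 + 0.1 * rng.standard_normal(m_star.shape)), 3)
        fitted, history = train(net, u_torso, u_endo, tcfg)
        te = history.test_indices
        recon = predict(fitted, u_torso)
        rel, _, _ = mean_relative_error(u_endo.values[:, te], recon.values[:, te])
        assert rel < 1.0

    def test_history_records_split_and_steps(self, small_dataset):
        u_torso, u_endo, _ = small_dataset
        net = init_linear(np.zeros((u_endo.n_channels, u_torso.n_channels)), 2)
        cfg = TrainConfig(n_iterations=10, seed=7)
        _, history = train(net, u_torso, u_endo, cfg)
        assert len(history.train_indices) + len(history.test_indices) == u_torso.n_samples
        assert len(history.steps) == len(history.objectives) - 1
        assert all(g in cfg.trial_steps for g in history.steps)
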