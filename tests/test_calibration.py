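import numpy as np
import pytest

import burstinfer as bi
from burstinfer.calibration import (
    CalibrationConfig,
    DEFAULT_PRIORS,
    MomentTargets,
    bootstrap_moment_errors,
    moment_error_statistic,
    moment_pseudo_likelihood,
    population_moment_equations,
    run_moment_mcmc,
)
from burstinfer.input_signal import TFInput
from burstinfer.moments import MOMENT_NAMES, propagate_conditional_moments

IDX = {n: i for i, n in enumerate(MOMENT_NAMES)}


class TestMomentEquations:
    def test_no_activation_means_zero_moments(self):
        model = bi.PromoterModel(gamma=0.0, q10=0.05, q12=0.001, q21=0.004, z1=0.01, z2=0.5)
        kin = bi.GeneKinetics(c1=1e-3, c2=1e-5, mean_A=0.1, cv_A=0.1)
        sig = bi.build_pulse_schedule(1, 40.0, amplitude_level=75)
        pred = population_moment_equations(model, kin, sig, np.linspace(0, 9000, 10))
        assert np.allclose(pred["mean_protein"], 0.0, atol=1e-10)
        assert np.allclose(pred["var_protein"], 0.0, atol=1e-10)

    def test_pinned_promoter_reduces_to_conditional_moments(self):
        """With the promoter locked in one state the population moments must
        equal the conditional-moment solution at that fixed rate."""
        z1 = 0.3
        model = bi.PromoterModel(gamma=0.0, q10=0.0, q12=0.0, q21=0.0, z1=z1, z2=0.0,
                                 p0=(0.0, 1.0, 0.0))
        kin = bi.GeneKinetics(c1=0.01, c2=1e-4, mean_A=0.05, cv_A=0.3)
        sig = TFInput(u0=0.0, k1=1.0, k2=1.0, schedule=())
        T = 1200.0
        pred = population_moment_equations(model, kin, sig, np.array([T]), rtol=1e-10, atol=1e-12)
        rm0 = np.zeros(13)
        rm0[IDX["A"]] = kin.mean_A
        rm0[IDX["A2"]] = kin.mean_A**2 * (1 + kin.cv_A**2)
        cond = propagate_conditional_moments(rm0, z1, kin, T)
        assert pred["mean_protein"][0] == pytest.approx(cond[IDX["N"]], rel=1e-7)
        var_cond = cond[IDX["N2"]] - cond[IDX["N"]] ** 2
        assert pred["var_protein"][0] == pytest.approx(var_cond, rel=1e-6)

    def test_matches_ssa_ensemble(self):
        """Population mean/variance vs an SSA ensemble (moderate copies)."""
        model = bi.PromoterModel(gamma=0.05, q10=0.055, q12=0.01, q21=0.04, z1=0.02, z2=0.2)
        kin = bi.GeneKinetics(c1=0.01, c2=1e-4, mean_A=0.02, cv_A=0.2)
        sig = bi.build_pulse_schedule(1, 20.0, amplitude_level=75)
        checks = np.array([600.0, 1500.0, 2400.0])
        n_cells = 3000
        rng = np.random.default_rng(17)
        A = bi.sample_translation_rates(kin, n_cells, rng)
        N = np.empty((n_cells, 3))
        M = np.empty((n_cells, 3))
        for i in range(n_cells):
            tr = bi.simulate_cell_ssa(model, kin, sig, float(A[i]), 3000.0,
                                      seed=200_000 + i, sample_times_s=checks, initial_state=0)
            N[i] = tr.sampled_protein
            M[i] = tr.sampled_mrna
        pred = population_moment_equations(model, kin, sig, checks)
        for j in range(3):
            se = N[:, j].std(ddof=1) / np.sqrt(n_cells)
            assert abs(N[:, j].mean() - pred["mean_protein"][j]) < 3 * se
            se_m = M[:, j].std(ddof=1) / np.sqrt(n_cells)
            assert abs(M[:, j].mean() - pred["mean_mrna"][j]) < 3 * se_m
            # variance comparison via SE of the sample variance
            v = N[:, j] - N[:, j].mean()
            se_var = np.sqrt(max((v**4).mean() - (v**2).mean() ** 2, 1e-12) / n_cells)
            assert abs(N[:, j].var(ddof=1) - pred["var_protein"][j]) < 3.5 * se_var


class TestBootstrap:
    def test_identical_cells_have_floored_ses(self):
        vals = np.tile(np.arange(5.0), (20, 1))
        t = np.arange(5.0)
        targets = bootstrap_moment_errors(vals, t, B=50, seed=0)
        assert np.all(targets.se_mean == 1e-6)
        assert np.all(targets.se_var == 1e-6)

    def test_iid_normal_se_matches_analytic(self):
        rng = np.random.default_rng(0)
        n, sigma = 200, 2.5
        vals = rng.normal(0, sigma, size=(n, 3))
        targets = bootstrap_moment_errors(vals, np.arange(3.0), B=1000, seed=1)
        expected = sigma / np.sqrt(n)
        assert np.allclose(targets.se_mean, expected, rtol=0.2)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(30, 4))
        a = bootstrap_moment_errors(vals, np.arange(4.0), B=100, seed=7)
        b = bootstrap_moment_errors(vals, np.arange(4.0), B=100, seed=7)
        assert np.array_equal(a.se_mean, b.se_mean)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_moment_errors(np.ones((20, 3)), np.arange(3.0), B=1, seed=0)


class TestPseudoLikelihoodAndError:
    def targets(self):
        t = np.arange(4.0)
        return MomentTargets(t_s=t, mean=np.array([1.0, 2, 3, 4]),
                             var=np.array([1.0, 1, 1, 1]),
                             se_mean=np.full(4, 0.5), se_var=np.full(4, 0.25))

    def test_perfect_prediction_scores_zero_misfit(self):
        tg = self.targets()
        assert moment_pseudo_likelihood(tg.mean, tg.var, tg) == 0.0
        assert moment_error_statistic(tg.mean, tg.var, tg) == (0.0, 0.0)

    def test_one_se_offset_costs_half(self):
        tg = self.targets()
        pred_mean = tg.mean.copy()
        pred_mean[0] += tg.se_mean[0]
        assert moment_pseudo_likelihood(pred_mean, tg.var, tg) == pytest.approx(-0.5)

    def test_constant_two_se_offset_gives_statistic_two(self):
        tg = self.targets()
        e_mean, e_var = moment_error_statistic(tg.mean + 2 * tg.se_mean, tg.var + 2 * tg.se_var, tg)
        assert e_mean == pytest.approx(2.0)
        assert e_var == pytest.approx(2.0)

    def test_score_ordering_matches_weighted_sse(self):
        rng = np.random.default_rng(3)
        tg = self.targets()
        scores, sses = [], []
        for _ in range(20):
            pm = tg.mean + rng.normal(0, 1, 4)
            pv = tg.var + rng.normal(0, 1, 4)
            scores.append(moment_pseudo_likelihood(pm, pv, tg))
            sses.append(np.sum(((pm - tg.mean) / tg.se_mean) ** 2)
                        + np.sum(((pv - tg.var) / tg.se_var) ** 2))
        assert np.array_equal(np.argsort(scores), np.argsort(sses)[::-1])

    def test_grid_mismatch_rejected(self):
        tg = self.targets()
        with pytest.raises(ValueError):
            moment_pseudo_likelihood(tg.mean[:2], tg.var[:2], tg)


class TestMCMC:
    def test_prior_only_map_matches_gamma_modes(self):
        sig = bi.build_pulse_schedule(1, 40.0, amplitude_level=75)
        cfg = CalibrationConfig(n_mcmc=4000, seed=4)
        rep = run_moment_mcmc(None, sig, cfg, prior_only=True)
        for name in ("c1", "mean_A"):
            shape, rate = DEFAULT_PRIORS[name]
            mode = (shape - 1) / rate
            assert rep.map_params[name] == pytest.approx(mode, rel=0.05)
        # exponential priors are nearly flat below their mean, so the joint
        # finite-sample MAP only constrains these components to the prior bulk
        for name in ("gamma", "q10", "q12", "q21", "z1", "z2"):
            shape, rate = DEFAULT_PRIORS[name]
            assert shape == 1.0  # exponential prior: analytic mode at 0
            assert 0 < rep.map_params[name] < 1.0 / rate  # below the prior mean

    def test_fixed_seed_gives_identical_chain(self):
        sig = bi.build_pulse_schedule(1, 40.0, amplitude_level=75)
        cfg = CalibrationConfig(n_mcmc=300, seed=11)
        a = run_moment_mcmc(None, sig, cfg, prior_only=True)
        b = run_moment_mcmc(None, sig, cfg, prior_only=True)
        assert a.trace.equals(b.trace)

    def test_two_stage_protocol_keeps_omega_fixed(self):
        sig = bi.build_pulse_schedule(1, 40.0, amplitude_level=75)
        cfg = CalibrationConfig(n_mcmc=200, seed=5, fixed={"c1": 2e-3, "mean_A": 0.07})
        kin = bi.GeneKinetics(c1=2e-3, c2=1.67e-5, mean_A=0.07, cv_A=0.02)
        rep = run_moment_mcmc(None, sig, cfg, init_kinetics=kin, prior_only=True)
        assert "c1" not in rep.map_params and "mean_A" not in rep.map_params
        assert rep.map_kinetics.c1 == 2e-3
        assert rep.map_kinetics.mean_A == 0.07
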