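import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import burstinfer as bi
from burstinfer.input_signal import TFInput
from burstinfer.moments import (
    ConditionalMomentPropagator,
    LogMoments,
    MOMENT_NAMES,
    initial_log_moments,
    lognormal_to_raw_moments,
    propagate_conditional_moments,
    raw_moments_to_lognormal,
)

IDX = {n: i for i, n in enumerate(MOMENT_NAMES)}


def make_rm(mu, sigma):
    return lognormal_to_raw_moments(LogMoments(np.asarray(mu), np.asarray(sigma)))


class TestLogNormalConversions:
    def test_point_mass_at_one(self):
        rm = make_rm([0.0, 0.0, 0.0], np.zeros((3, 3)))
        assert np.allclose(rm, 1.0)

    def test_first_moment_formula(self):
        rm = make_rm([np.log(10.0), 0.0, 0.0], np.diag([0.25, 0.0, 0.0]))
        assert rm[IDX["M"]] == pytest.approx(10.0 * np.exp(0.125))
        assert rm[IDX["M2"]] == pytest.approx(100.0 * np.exp(0.5))

    def test_moments_match_sampling_oracle(self):
        rng = np.random.default_rng(0)
        mu = np.array([0.5, 1.0, -2.0])
        A = rng.normal(size=(3, 3)) * 0.3
        sigma = A @ A.T + 0.05 * np.eye(3)
        rm = make_rm(mu, sigma)
        n = 1_000_000
        X = np.exp(rng.multivariate_normal(mu, sigma, size=n))
        P = np.array([[1,0,0],[0,1,0],[2,0,0],[1,1,0],[1,0,1],[0,2,0],[0,1,1],
                      [2,0,1],[1,1,1],[1,0,2],[2,0,2],[0,0,1],[0,0,2]], dtype=float)
        for k in range(13):
            samples = np.prod(X ** P[k], axis=1)
            se = samples.std(ddof=1) / np.sqrt(n)
            assert abs(samples.mean() - rm[k]) < 3 * se + 1e-12, MOMENT_NAMES[k]

    def test_roundtrip_is_identity(self):
        mu = np.array([1.0, 2.0, -2.0])
        sigma = 0.1 * np.eye(3)
        lm = raw_moments_to_lognormal(make_rm(mu, sigma))
        assert np.allclose(lm.mu, mu, atol=1e-10)
        assert np.allclose(lm.sigma, sigma, atol=1e-10)

    def test_zero_variance_hits_floor(self):
        rm = np.ones(13)  # E[M]=E[M^2]=1 etc: zero implied log-variance
        lm = raw_moments_to_lognormal(rm)
        assert lm.sigma[0, 0] == pytest.approx(1e-12, rel=1.0)
        assert lm.mu[0] == pytest.approx(0.0, abs=1e-9)

    def test_recovery_from_sampled_moments(self):
        rng = np.random.default_rng(1)
        mu = np.array([1.2, 3.0, -2.3])
        sigma = np.diag([0.09, 0.04, 0.01])
        n = 1_000_000
        X = np.exp(rng.multivariate_normal(mu, sigma, size=n))
        rm = np.array([
            X[:, 0].mean(), X[:, 1].mean(), (X[:, 0] ** 2).mean(),
            (X[:, 0] * X[:, 1]).mean(), (X[:, 0] * X[:, 2]).mean(),
            (X[:, 1] ** 2).mean(), (X[:, 1] * X[:, 2]).mean(),
            (X[:, 0] ** 2 * X[:, 2]).mean(), (X[:, 0] * X[:, 1] * X[:, 2]).mean(),
            (X[:, 0] * X[:, 2] ** 2).mean(), (X[:, 0] ** 2 * X[:, 2] ** 2).mean(),
            X[:, 2].mean(), (X[:, 2] ** 2).mean(),
        ])
        lm = raw_moments_to_lognormal(rm)
        se_mu = sigma.diagonal() ** 0.5 / np.sqrt(n) * 3  # rough SE of log-mean
        assert np.all(np.abs(lm.mu - mu) < 3 * se_mu + 1e-3)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_roundtrip_property(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.normal(0, 2, 3)
        d = rng.uniform(0.01, 0.5, 3)
        sigma = np.diag(d)
        lm = raw_moments_to_lognormal(make_rm(mu, sigma))
        assert np.allclose(lm.mu, mu, atol=1e-9)
        assert np.allclose(lm.sigma, sigma, atol=1e-9)


class TestPropagation:
    kin = bi.GeneKinetics(c1=0.0013, c2=1.67e-5, mean_A=0.1, cv_A=0.02)

    def test_zero_dt_is_identity(self):
        rm = make_rm([0.1, 0.2, -2.0], 0.05 * np.eye(3))
        out = propagate_conditional_moments(rm, 0.5, self.kin, 0.0)
        assert np.array_equal(out, rm)

    def test_mrna_mean_matches_closed_form(self):
        # start from zero M,N moments with A a point mass at 1
        rm = np.zeros(13)
        rm[IDX["A"]] = 1.0
        rm[IDX["A2"]] = 1.0
        z, t = 0.7, 1500.0
        out = propagate_conditional_moments(rm, z, self.kin, t)
        expected = z / self.kin.c1 * (1 - np.exp(-self.kin.c1 * t))
        assert out[IDX["M"]] == pytest.approx(expected, abs=1e-8 * expected)

    def test_protein_mean_matches_closed_form_deterministic_A(self):
        # with A = a fixed, E[N]' = a E[M]; integrate the cascade analytically
        a, z, t = 0.05, 0.3, 2000.0
        c1, c2 = 0.01, 1e-4
        kin = bi.GeneKinetics(c1=c1, c2=c2, mean_A=a, cv_A=0.0)
        rm = np.zeros(13)
        rm[IDX["A"]] = a
        rm[IDX["A2"]] = a * a
        out = propagate_conditional_moments(rm, z, kin, t)
        mss = z / c1
        # E[N](t) for the two-stage cascade from empty initial condition
        en = a * mss * (
            (1 - np.exp(-c2 * t)) / c2 - (np.exp(-c2 * t) - np.exp(-c1 * t)) / (c1 - c2)
        )
        assert out[IDX["N"]] == pytest.approx(en, rel=1e-8)

    def test_semigroup_property(self):
        rm = make_rm([0.5, 2.0, -2.3], np.diag([0.2, 0.3, 0.01]))
        prop = ConditionalMomentPropagator(self.kin)
        a = prop.propagate(prop.propagate(rm, 0.7, 400.0), 0.7, 600.0)
        b = prop.propagate(rm, 0.7, 1000.0)
        assert np.allclose(a, b, rtol=1e-9, atol=1e-12)

    def test_implied_variances_stay_positive(self):
        rm = make_rm([0.0, 0.0, -2.3], np.diag([0.5, 0.5, 0.01]))
        prop = ConditionalMomentPropagator(self.kin)
        for z in [0.0, 0.0035, 0.728]:
            out = prop.propagate(rm, z, 166.7)
            lm = raw_moments_to_lognormal(out)
            assert np.all(np.diag(lm.sigma) >= 0)

    def test_matches_ssa_ensemble_with_fixed_rate_path(self):
        """Conditional moments vs an SSA ensemble sharing one z-path."""
        kin = bi.GeneKinetics(c1=0.01, c2=1e-4, mean_A=0.02, cv_A=0.2)
        z = 0.2
        T = 800.0
        n_runs = 4000
        # pinned-active promoter reproduces the conditional system at fixed z
        model = bi.PromoterModel(gamma=0.0, q10=0.0, q12=0.0, q21=0.0, z1=z, z2=0.0,
                                 p0=(0.0, 1.0, 0.0))
        sig = TFInput(u0=0.0, k1=1.0, k2=1.0, schedule=())
        rng = np.random.default_rng(3)
        A = bi.sample_translation_rates(kin, n_runs, rng)
        M = np.empty(n_runs)
        N = np.empty(n_runs)
        for i in range(n_runs):
            traj = bi.simulate_cell_ssa(model, kin, sig, float(A[i]), T, seed=70_000 + i,
                                        sample_times_s=np.array([T]), initial_state=1)
            M[i], N[i] = traj.sampled_mrna[0], traj.sampled_protein[0]
        rm0 = np.zeros(13)
        rm0[IDX["A"]] = kin.mean_A
        rm0[IDX["A2"]] = kin.mean_A**2 * (1 + kin.cv_A**2)
        out = propagate_conditional_moments(rm0, z, kin, T)
        for name, sample in [("M", M), ("N", N)]:
            se = sample.std(ddof=1) / np.sqrt(n_runs)
            assert abs(sample.mean() - out[IDX[name]]) < 3 * se
        for name, sample in [("M2", M**2), ("N2", N**2)]:
            se = sample.std(ddof=1) / np.sqrt(n_runs)
            assert abs(sample.mean() - out[IDX[name]]) < 3.5 * se


class TestInitialMoments:
    def test_pseudo_moments_are_configurable(self):
        kin = bi.GeneKinetics(c1=0.01, c2=1e-4, mean_A=0.05, cv_A=0.1)
        lm = initial_log_moments(kin, pseudo_mean=0.2, pseudo_cv=0.5)
        rm = lognormal_to_raw_moments(lm)
        assert rm[IDX["M"]] == pytest.approx(0.2, rel=1e-9)
        assert rm[IDX["A"]] == pytest.approx(0.05, rel=1e-9)

    def test_overflow_raises_named_error(self):
        lm = LogMoments(np.array([400.0, 0.0, 0.0]), np.eye(3))
        with pytest.raises(OverflowError, match="M"):
            lognormal_to_raw_moments(lm)
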