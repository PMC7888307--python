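import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import burstinfer as bi
from burstinfer.features import (
    ActivityThreshold,
    classify_responder,
    cluster_condition_profiles,
    extract_cell_features,
    path_functionals,
    posterior_rate_curve,
    regress_output_on_time_transcribing,
    summarize_population,
)
from burstinfer.smc import PosteriorSample

T_S = 150 * 60.0
MODEL = bi.PromoterModel(gamma=0.01, q10=0.01, q12=0.001, q21=0.004, z1=1.0, z2=1.0)
THR = ActivityThreshold(reference_max_rate=1.0)


def make_posterior(paths, weights):
    return PosteriorSample(
        paths=[(np.asarray(t, dtype=float), np.asarray(s, dtype=int)) for t, s in paths],
        weights=np.asarray(weights, dtype=float),
        log_marginal_likelihood=0.0,
        stable=True,
        T_s=T_S,
    )


ALWAYS_ACTIVE = ([0.0], [1])
NEVER_ACTIVE = ([0.0], [0])


class TestResponderClassification:
    def test_fully_active_posterior_is_responder(self):
        post = make_posterior([ALWAYS_ACTIVE] * 4, np.full(4, 0.25))
        pa, flag = classify_responder(post, THR, MODEL)
        assert pa == 1.0 and flag

    def test_never_active_posterior_is_not(self):
        post = make_posterior([NEVER_ACTIVE] * 4, np.full(4, 0.25))
        pa, flag = classify_responder(post, THR, MODEL)
        assert pa == 0.0 and not flag

    def test_one_minute_activity_fails_two_minute_rule(self):
        path = ([0.0, 60.0, 120.0], [0, 1, 0])  # active exactly 1 min
        post = make_posterior([path] * 3, np.full(3, 1 / 3))
        pa, flag = classify_responder(post, THR, MODEL)
        assert pa == 0.0 and not flag

    def test_threshold_excludes_weak_states(self):
        weak = bi.PromoterModel(gamma=0.01, q10=0.01, q12=0.001, q21=0.004, z1=0.05, z2=1.0)
        path = ([0.0], [1])  # in the weak state the whole time
        post = make_posterior([path], [1.0])
        pa, _ = classify_responder(post, ActivityThreshold(reference_max_rate=1.0), weak)
        assert pa == 0.0  # z1 = 0.05 < 0.2 * 1.0


class TestCellFeatures:
    def test_always_active_path(self):
        post = make_posterior([ALWAYS_ACTIVE], [1.0])
        f = extract_cell_features(post, THR, MODEL)
        assert f["time_to_activate_min"] == 0.0
        assert f["time_active_min"] == pytest.approx(150.0)
        assert f["transcriptional_output"] == pytest.approx(9000.0)

    def test_never_active_path(self):
        post = make_posterior([NEVER_ACTIVE], [1.0])
        f = extract_cell_features(post, THR, MODEL)
        assert f["time_active_min"] == 0.0
        assert f["transcriptional_output"] == 0.0
        assert np.isnan(f["time_to_activate_min"])

    def test_two_path_mixture_weighted_average(self):
        post = make_posterior([ALWAYS_ACTIVE, NEVER_ACTIVE], [0.5, 0.5])
        f = extract_cell_features(post, THR, MODEL)
        assert f["time_active_min"] == pytest.approx(75.0)
        assert f["transcriptional_output"] == pytest.approx(4500.0)
        # responder-conditioned time to activate averages qualifying paths only
        assert f["time_to_activate_min"] == 0.0
        assert f["response_probability"] == pytest.approx(0.5)

    def test_unstable_cell_has_no_features(self):
        post = make_posterior([ALWAYS_ACTIVE], [1.0])
        post.stable = False
        with pytest.raises(ValueError):
            extract_cell_features(post, THR, MODEL)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_time_accounting_and_output_exactness(self, seed):
        rng = np.random.default_rng(seed)
        n_jumps = rng.integers(0, 12)
        times = np.sort(rng.uniform(0, T_S, n_jumps))
        states = rng.integers(0, 3, n_jumps + 1)
        f = path_functionals(np.concatenate(([0.0], times)), states, T_S, MODEL, THR)
        assert f["time_in_state_s"].sum() == pytest.approx(T_S, abs=1e-6)
        # exact segment-sum output oracle
        bounds = np.concatenate(([0.0], times, [T_S]))
        expected = float(np.sum(MODEL.z[states] * np.diff(bounds)))
        assert f["output_molecules"] == pytest.approx(expected, rel=1e-12)
        assert f["time_transcribing_s"] >= f["time_active_s"] - 1e-9


class TestPopulationSummary:
    def frame(self, outputs, responders=None):
        n = len(outputs)
        return pd.DataFrame({
            "transcriptional_output": outputs,
            "responder": responders if responders is not None else [True] * n,
            "time_active_min": np.linspace(10, 20, n),
            "time_to_activate_min": np.linspace(1, 2, n),
        })

    def test_cv2_of_one_and_three_is_quarter(self):
        s = summarize_population(self.frame([1.0, 3.0]))
        assert s["output_noise_cv2"] == pytest.approx(0.25)

    def test_identical_cells_have_zero_noise(self):
        s = summarize_population(self.frame([2.0, 2.0, 2.0]))
        assert s["output_noise_cv2"] == 0.0

    def test_sample_variance_variant(self):
        s = summarize_population(self.frame([1.0, 3.0]), cv2_population=False)
        assert s["output_noise_cv2"] == pytest.approx(0.5)

    def test_triangle_rate_curve_peak_location(self):
        t_grid = np.linspace(0, 9000, 301)
        lam = np.interp(t_grid, [0, 2400, 9000], [0, 5.0, 0])  # peak at 40 min
        s = summarize_population(self.frame([1.0, 2.0]),
                                 rate_curves=np.tile(lam, (2, 1)), t_grid_s=t_grid)
        assert s["tau_max_min"] == pytest.approx(40.0, abs=0.5)
        assert s["lambda_max"] == pytest.approx(5.0, rel=1e-6)

    def test_zero_responders_leaves_conditioned_features_null(self):
        s = summarize_population(self.frame([1.0, 2.0], responders=[False, False]))
        assert np.isnan(s["mean_time_to_activate_min"])
        assert s["percent_responders"] == 0.0


class TestRegression:
    def test_exactly_proportional_data(self):
        df = pd.DataFrame({"time_transcribing_min": [1.0, 2, 3, 4],
                           "transcriptional_output": [5.0, 10, 15, 20]})
        r = regress_output_on_time_transcribing(df)
        assert r["slope"] == pytest.approx(5.0)
        assert r["r2"] == pytest.approx(1.0)

    def test_all_zero_outputs_flagged_degenerate(self):
        df = pd.DataFrame({"time_transcribing_min": [1.0, 2, 3],
                           "transcriptional_output": [0.0, 0, 0]})
        r = regress_output_on_time_transcribing(df)
        assert r["slope"] == 0.0
        assert r["r2"] == 1.0
        assert r["degenerate"]

    def test_fast_promoter_output_is_proportional_to_time_transcribing(self):
        """A promoter that equilibrates quickly between its two permissive
        states behaves like a single effective rate, so single-cell output
        scales proportionally with time transcribing (true paths, no
        inference).  Activation must be rate-limiting for the regressor to
        vary between cells."""
        cfg = bi.BenchmarkConfig(
            kappa=1.0, n_cells=100, seed=5,
            gamma=2e-6, q10=0.01, q12_base=0.05, q21_base=0.05, z1=0.05, z2=0.15,
            c1=0.005, c2=1e-4, mean_A=0.02, cv_A=0.1, eta=0.05,
        )
        ds = bi.generate_benchmark_dataset(cfg)
        r = regress_output_on_time_transcribing(ds.true_features)
        assert r["r2"] >= 0.9
        # effective rate is the fast-exchange average of the two states
        assert r["slope"] == pytest.approx(0.1 * 60.0, rel=0.15)

    def test_posterior_rate_curve_matches_path_mixture(self):
        post = make_posterior([ALWAYS_ACTIVE, NEVER_ACTIVE], [0.25, 0.75])
        lam = posterior_rate_curve(post, MODEL, np.array([0.0, 100.0, T_S - 1]))
        assert np.allclose(lam, 0.25 * MODEL.z1)


class TestClustering:
    def test_identical_rows_merge_first_at_height_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 4))
        X[3] = X[1]
        df = pd.DataFrame(X, index=list("abcde"))
        res = cluster_condition_profiles(df)
        assert res["linkage"][0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(res["linkage"][0, 0]), int(res["linkage"][0, 1])} == {1, 3}

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, size=(5, 3)), rng.normal(5, 0.1, size=(5, 3))])
        df = pd.DataFrame(X)
        res = cluster_condition_profiles(df, n_clusters=2)
        labels = res["labels"].to_numpy()
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_zero_responder_rows_excluded(self):
        df = pd.DataFrame({
            "percent_responders_10": [10.0, 0.0, 20.0],
            "percent_responders_50": [30.0, 5.0, 25.0],
            "output": [1.0, 2.0, 3.0],
        }, index=["x", "y", "z"])
        res = cluster_condition_profiles(df, responder_columns=[
            "percent_responders_10", "percent_responders_50"])
        assert "y" not in res["rows"]

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=4), "b": np.ones(4)})
        res = cluster_condition_profiles(df)
        assert res["dropped_features"] == ["b"]
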