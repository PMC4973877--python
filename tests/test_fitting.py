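"""Tests of weighted regression, grid search, permutations and maps."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from predrep.fitting import (
    grid_search,
    permutation_test,
    population_maps,
    read_trials,
    response_significance,
    weighted_regression,
    write_trials,
    counts_from_times,
)
from predrep.ib import sufficient_statistic_representation
from predrep.prediction import trace_trials
from predrep.synthetic import BlockSpec, SyntheticNeuron, generate_block, generate_counts


def _linear_trials(rep, a=2.0, b=3.0, seed=0, sigma=0.0, p_highs=(0.1, 0.5, 0.9)):
    """Blocks with counts exactly (or noisily) affine in expected error."""
    rng = np.random.default_rng(seed)
    frames = []
    for i, p in enumerate(p_highs):
        codes = generate_block(BlockSpec(p_high=p, seed=seed + i))
        df = pd.DataFrame(
            {
                "neuron_id": "n0",
                "block_id": i,
                "condition": p,
                "trial_index": np.arange(400),
                "tone": codes,
            }
        )
        frames.append(df)
    trials = pd.concat(frames, ignore_index=True)
    trace = trace_trials(rep, trials, burn_in=50)
    trials = trials[trials["trial_index"] >= 50].reset_index(drop=True)
    counts = a * trace.expected_error + b
    counts = counts + sigma * rng.standard_normal(len(counts))
    trials["spike_count"] = counts
    return trials, trace


class TestWeightedRegression:
    def test_exact_linear_recovery(self, world4):
        rep = sufficient_statistic_representation(world4)
        trials, trace = _linear_trials(rep, a=2.0, b=3.0)
        one = trials[trials["tone"] == 1]
        fit = weighted_regression(one, trace)
        assert fit.weighted_r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(3.0, abs=1e-9)

    def test_matches_statsmodels_wls_on_expanded_set(self, curve4):
        """Dual route: the histogram-contraction fit equals an explicit
        WLS on the expanded (state, trial) set."""
        rep = curve4.at_complexity(1.2)
        trials, trace = _linear_trials(rep, a=1.5, b=2.0, sigma=0.5)
        one = trials[trials["tone"] == 1].reset_index(drop=True)
        fit = weighted_regression(one, trace)

        rows = np.nonzero(trace.tone == 1)[0]
        w = trace.weights[rows].ravel()
        x = trace.errors[rows].ravel()
        y = np.repeat(one["spike_count"].to_numpy(), trace.weights.shape[1])
        keep = w > 0
        model = sm.WLS(y[keep], sm.add_constant(x[keep]), weights=w[keep]).fit()
        assert fit.intercept == pytest.approx(model.params[0], abs=1e-8)
        assert fit.slope == pytest.approx(model.params[1], abs=1e-8)
        ybar = np.average(y[keep], weights=w[keep])
        ss_tot = np.sum(w[keep] * (y[keep] - ybar) ** 2)
        ss_res = np.sum(w[keep] * model.resid**2)
        assert fit.weighted_r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-8)

    def test_deterministic_rep_reduces_to_ols(self, world4):
        rep = sufficient_statistic_representation(world4)
        trials, trace = _linear_trials(rep, a=2.0, b=1.0, sigma=1.0)
        one = trials[trials["tone"] == 1].reset_index(drop=True)
        fit = weighted_regression(one, trace)
        rows = np.nonzero(trace.tone == 1)[0]
        x = trace.expected_error[rows]
        ols = sm.OLS(one["spike_count"].to_numpy(), sm.add_constant(x)).fit()
        assert fit.slope == pytest.approx(ols.params[1], abs=1e-9)
        assert fit.weighted_r2 == pytest.approx(ols.rsquared, abs=1e-9)

    def test_shuffled_counts_near_zero_r2(self, world4):
        rep = sufficient_statistic_representation(world4)
        trials, trace = _linear_trials(rep, a=0.0, b=5.0, sigma=1.0, seed=3)
        one = trials[trials["tone"] == 1]
        fit = weighted_regression(one, trace)
        assert fit.weighted_r2 <= 0.05

    def test_zero_count_variance_warns_r2_zero(self, world4):
        rep = sufficient_statistic_representation(world4)
        trials, trace = _linear_trials(rep, a=0.0, b=4.0)
        one = trials[trials["tone"] == 1]
        with pytest.warns(UserWarning, match="zero variance"):
            fit = weighted_regression(one, trace)
        assert fit.weighted_r2 == 0.0

    def test_too_few_trials(self, world4):
        rep = sufficient_statistic_representation(world4)
        trials, trace = _linear_trials(rep)
        with pytest.raises(ValueError, match="3 trials"):
            weighted_regression(trials.iloc[:2], trace)


class TestGridSearch:
    def test_surface_shape_and_determinism(self, bank14):
        exp_trials = _make_synthetic(bank14, seed=4)
        g1 = grid_search(exp_trials, bank14, "high")
        g2 = grid_search(exp_trials, bank14, "high")
        assert g1.r2.shape == (14, 40)
        np.testing.assert_array_equal(g1.r2, g2.r2)
        assert g1.rmax2 == g1.r2.max()
        assert g1.good_set.sum() >= 1

    def test_recovery_of_generating_member(self, bank14):
        trials = _make_synthetic(bank14, seed=5)
        g = grid_search(trials, bank14, "high")
        i = list(g.n_values).index(10)
        j = int(np.argmin(np.abs(bank14.curves[10].complexities - 2.0)))
        assert g.good_set[i, j]
        assert g.argmax[0] >= 8

    def test_null_neuron_small_positive_rmax2(self, bank14):
        trials = _make_synthetic(bank14, seed=6, a=0.0)
        g = grid_search(trials, bank14, "high")
        assert 0.0 < g.rmax2 < 0.1


def _make_synthetic(bank, seed=0, a=2.0, b=3.0, sigma=1.0, n_star=10,
                    c_star=2.0):
    rep = bank.curves[n_star].at_complexity(c_star)
    neuron = SyntheticNeuron(a=a, b=b, rep=rep, noise="gaussian", sigma=sigma)
    sequences = {
        i: (p, generate_block(BlockSpec(p_high=p, seed=seed * 10 + i)))
        for i, p in enumerate((0.1, 0.5, 0.9))
    }
    return generate_counts(sequences, neuron, seed=seed)


class TestPermutationTest:
    def test_linear_neuron_significant(self, bank14):
        trials = _make_synthetic(bank14, seed=7)
        res = permutation_test(trials, bank14, "high", n_perm=20, seed=1)
        assert res.significant
        assert len(res.permuted_rmax2) == 20
        assert res.observed_rmax2 > res.permuted_rmax2.max()

    def test_zero_permutations_rejected(self, bank14):
        trials = _make_synthetic(bank14, seed=8)
        with pytest.raises(ValueError):
            permutation_test(trials, bank14, "high", n_perm=0)

    def test_block_relabeling_invariance(self, bank14):
        trials = _make_synthetic(bank14, seed=9)
        relabeled = trials.copy()
        relabeled["block_id"] = relabeled["block_id"].map({0: 10, 1: 11, 2: 12})
        a = permutation_test(trials, bank14, "high", n_perm=5, seed=2)
        b = permutation_test(relabeled, bank14, "high", n_perm=5, seed=2)
        assert a.observed_rmax2 == pytest.approx(b.observed_rmax2, abs=1e-12)
        np.testing.assert_allclose(a.permuted_rmax2, b.permuted_rmax2,
                                   atol=1e-12)


class TestResponseSignificance:
    def test_strong_response_detected(self):
        rng = np.random.default_rng(0)
        assert response_significance(rng.poisson(10, 100), rng.poisson(1, 100))

    def test_identical_samples_not_significant(self):
        x = np.full(50, 3.0)
        assert not response_significance(x, x)

    def test_one_sided(self):
        rng = np.random.default_rng(1)
        assert not response_significance(rng.poisson(1, 100),
                                         rng.poisson(10, 100))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            response_significance([], [1, 2])


class TestPopulationMaps:
    def test_single_case_map_is_binary_good_set(self, bank14):
        g = grid_search(_make_synthetic(bank14, seed=11), bank14, "high")
        maps = population_maps([g], min_rmax2=0.1)
        assert maps.n_cases == 1
        assert set(np.unique(maps.by_n_complexity)) <= {0.0, 1.0}

    def test_fractions_bounded(self, bank14):
        grids = [
            grid_search(_make_synthetic(bank14, seed=s), bank14, "high")
            for s in (12, 13, 14)
        ]
        maps = population_maps(grids, min_rmax2=0.1)
        for arr in (maps.by_complexity_power, maps.by_n_complexity,
                    maps.by_n_power):
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_homogeneous_population_concentrates(self, bank14):
        """A population all generated at (N*=12, C*=2.5) marks long
        memories and >= 2 bits of complexity in the majority region."""
        grids = [
            grid_search(
                _make_synthetic(bank14, seed=s, n_star=12, c_star=2.5),
                bank14, "high",
            )
            for s in range(6)
        ]
        maps = population_maps(grids, min_rmax2=0.1)
        centers = 0.5 * (maps.complexity_edges[:-1] + maps.complexity_edges[1:])
        majority = maps.by_n_complexity > 0.5
        marked_n = maps.n_values[majority.any(axis=1)]
        marked_c = centers[majority.any(axis=0)]
        assert marked_n.max() >= 10
        assert marked_c.max() >= 2.0

    def test_empty_filter_rejected(self, bank14):
        g = grid_search(_make_synthetic(bank14, seed=15, a=0.0), bank14, "high")
        with pytest.raises(ValueError, match="filter"):
            population_maps([g], min_rmax2=0.9)


class TestTrialIO:
    def test_round_trip_and_validation(self, tmp_path, bank14):
        trials = _make_synthetic(bank14, seed=16)
        trials = trials.assign(freq_label="high")
        path = tmp_path / "trials.tsv"
        write_trials(trials, path, header_comments=["unit test"])
        again = read_trials(path)
        assert len(again) == len(trials)
        np.testing.assert_allclose(
            again["spike_count"], trials["spike_count"], atol=1e-12
        )

    def test_bad_condition_rejected(self, tmp_path):
        df = pd.DataFrame(
            {
                "neuron_id": ["a"], "freq_label": ["low"], "block_id": [0],
                "condition": [0.25], "trial_index": [0], "tone": ["low"],
                "spike_count": [1],
            }
        )
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="condition"):
            read_trials(path)

    def test_counts_from_times_window(self):
        times = "5.0;100.2;329.9;330.0;500"
        assert counts_from_times(times, (0.0, 330.0)) == 3
        assert counts_from_times(times, (260.0, 330.0)) == 1
        assert counts_from_times("", (0.0, 330.0)) == 0
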