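"""Summaries, rate estimation, and model-vs-data comparisons."""

import math

import numpy as np
import pytest

from dropstat import (
    DomainError,
    DropletArray,
    SimulationDesign,
    SuspensionSpec,
    estimate_lambda,
    lln_demonstration,
    model_fit_error,
    replicate_experiment,
    simulate_droplet_array,
    single_target_model_check,
    summarize_array,
)


def tiny_array(totals, targets):
    n = len(totals)
    return DropletArray(
        row=np.zeros(n, dtype=np.int64),
        col=np.arange(n, dtype=np.int64),
        total_cells=np.asarray(totals, dtype=np.int64),
        target_cells=np.asarray(targets, dtype=np.int64),
    )


class TestSummarize:
    def test_all_empty_array(self):
        summary = summarize_array(tiny_array([0, 0, 0], [0, 0, 0]))
        assert summary.occupancy_count == 0
        assert summary.lambda_hat == 0.0
        assert summary.pmf_cells.tolist() == [1.0]

    def test_hand_counted_example(self):
        summary = summarize_array(tiny_array([0, 1, 2], [0, 1, 0]))
        assert summary.p_d_hat == pytest.approx(2 / 3)
        assert summary.lambda_hat == pytest.approx(1.0)
        assert summary.single_target_count == 1
        assert summary.strict_single_target_count == 1

    def test_strict_convention_excludes_coencapsulated_targets(self):
        # one droplet holds a target plus a bystander cell: counted by the
        # default convention, excluded by the strict one
        summary = summarize_array(tiny_array([2], [1]))
        assert summary.single_target_count == 1
        assert summary.strict_single_target_count == 0

    def test_empirical_pmfs_sum_to_one(self):
        summary = summarize_array(tiny_array([0, 1, 2, 5], [0, 1, 2, 3]))
        assert math.fsum(summary.pmf_cells) == pytest.approx(1.0, abs=1e-12)
        assert math.fsum(summary.pmf_targets) == pytest.approx(1.0, abs=1e-12)

    def test_consistency_at_large_n(self):
        design = SimulationDesign(
            suspension=SuspensionSpec(1.0e5 / 0.77, target_fraction=0.1),
            n_droplets=100_000,
            seed=21,
        )
        # concentration chosen so λ = 1.0 with the default 7.7 nl droplet
        summary = summarize_array(simulate_droplet_array(design))
        assert abs(summary.lambda_hat - 1.0) < 0.01


class TestEstimateLambda:
    def test_zero_counts_collapse_wald_interval(self):
        est = estimate_lambda(summarize_array(tiny_array([0, 0], [0, 0])))
        assert (est.estimate, est.ci_low, est.ci_high) == (0.0, 0.0, 0.0)

    def test_estimate_is_exactly_the_sample_mean(self):
        totals = [0, 1, 2, 3, 0, 1]
        est = estimate_lambda(summarize_array(tiny_array(totals, [0] * 6)))
        assert est.estimate == pytest.approx(sum(totals) / len(totals))

    def test_interval_width_shrinks_as_root_n(self):
        widths = []
        for n, seed in [(100, 1), (10_000, 1)]:
            design = SimulationDesign(
                suspension=SuspensionSpec(1.0e5), n_droplets=n, seed=seed
            )
            est = estimate_lambda(summarize_array(simulate_droplet_array(design)))
            widths.append(est.ci_high - est.ci_low)
        assert widths[1] < widths[0] / 5

    def test_mean_of_estimates_unbiased_in_low_rate_regime(self):
        # λ_target = 0.05: the 1.0e5 cells/ml, ~6.5% target mixture regime
        design = SimulationDesign(
            suspension=SuspensionSpec(1.0e5 / 0.77 * 0.05), n_droplets=100, seed=77
        )
        summaries = replicate_experiment(design, 1000)
        estimates = np.array([s.lambda_hat for s in summaries])
        se = math.sqrt(0.05 / 100 / 1000)
        assert abs(estimates.mean() - 0.05) < 3 * se

    def test_score_interval_never_collapses(self):
        est = estimate_lambda(
            summarize_array(tiny_array([0, 0], [0, 0])), method="score"
        )
        assert est.ci_low == 0.0 and est.ci_high > 0.0

    def test_exact_interval_brackets_wald(self):
        summary = summarize_array(tiny_array([1, 0, 2, 1], [0] * 4))
        exact = estimate_lambda(summary, method="exact")
        assert exact.ci_low < summary.lambda_hat < exact.ci_high

    def test_unknown_method_rejected(self):
        with pytest.raises(DomainError):
            estimate_lambda(summarize_array(tiny_array([1], [0])), method="bogus")


class TestModelFitError:
    def test_identical_pmfs(self):
        assert model_fit_error([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_symmetric_and_support_unioned(self):
        a, b = [0.9, 0.1], [0.8, 0.1, 0.1]
        assert model_fit_error(a, b) == model_fit_error(b, a) == pytest.approx(10.0)

    def test_simulated_versus_fitted_poisson_is_tight_at_scale(self):
        from scipy import stats

        design = SimulationDesign(
            suspension=SuspensionSpec(1.0e5), n_droplets=100_000, seed=8
        )
        summary = summarize_array(simulate_droplet_array(design))
        support = np.arange(len(summary.pmf_cells))
        model = stats.poisson.pmf(support, summary.lambda_hat)
        assert model_fit_error(summary.pmf_cells, model) < 1.0


class TestSingleTargetCheck:
    def test_no_targets_agree_exactly(self):
        design = SimulationDesign(
            suspension=SuspensionSpec(1.0e5, target_fraction=0.0),
            n_droplets=1000,
            seed=1,
        )
        summary = summarize_array(simulate_droplet_array(design))
        check = single_target_model_check(summary, design)
        assert check.empirical_pct == check.combined_pct == check.marginal_pct == 0.0

    def test_empirical_matches_thinned_marginal_at_scale(self):
        design = SimulationDesign(
            suspension=SuspensionSpec(1.0e5, target_fraction=0.5),
            n_droplets=100_000,
            seed=6,
        )
        summary = summarize_array(simulate_droplet_array(design))
        check = single_target_model_check(summary, design)
        assert check.error_marginal_pp < 1.0

    def test_combined_law_discounts_by_occupancy(self):
        # the combined form multiplies the marginal by P(occupied) < 1, a
        # structural gap reported rather than hidden
        design = SimulationDesign(
            suspension=SuspensionSpec(1.0e5, target_fraction=0.5),
            n_droplets=1000,
            seed=6,
        )
        summary = summarize_array(simulate_droplet_array(design))
        check = single_target_model_check(summary, design)
        assert check.combined_pct < check.marginal_pct

    def test_model_probability_never_exceeds_inverse_e(self):
        for fraction in (0.1, 0.3, 0.5, 1.0):
            design = SimulationDesign(
                suspension=SuspensionSpec(2.0e5, target_fraction=fraction),
                n_droplets=100,
                seed=1,
            )
            summary = summarize_array(simulate_droplet_array(design))
            check = single_target_model_check(summary, design)
            assert check.combined_pct <= 100 * math.exp(-1) + 1e-9


class TestLlnDemonstration:
    def test_distance_decreases_from_ten_to_one_hundred(self):
        for p in (0.583, 0.873):
            table = lln_demonstration(p, [10, 25, 50, 100])
            assert table["ks_distance"].is_monotonic_decreasing

    def test_distance_vanishes_for_large_n(self):
        table = lln_demonstration(0.5, [10, 10_000])
        assert table["ks_distance"].iloc[-1] < 0.01

    def test_exact_table_is_deterministic(self):
        a = lln_demonstration(0.583, [10, 100])
        b = lln_demonstration(0.583, [10, 100])
        assert a.equals(b)

    def test_monte_carlo_column_tracks_exact_enumeration(self):
        table = lln_demonstration(0.583, [10, 100], n_replicates=5000, seed=1)
        assert (table["ks_distance_mc"] - table["ks_distance"]).abs().max() < 0.05

    def test_non_increasing_n_values_rejected(self):
        with pytest.raises(DomainError):
            lln_demonstration(0.5, [100, 10])
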