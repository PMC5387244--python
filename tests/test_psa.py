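import dataclasses

import numpy as np
import pytest

from coarctcost.parameters import CostParam, InfeasibleMomentsError, ProbParam
from coarctcost.psa import (
    PSAResult,
    fit_distributions,
    iterations_table,
    run_psa,
    sample_parameters,
    summarize_psa,
)
from coarctcost.tree import total_cost

from .conftest import PUBLISHED_TABLE


def _zero_sd(params):
    changes = {}
    for name, p in params.items():
        cls = ProbParam if isinstance(p, ProbParam) else CostParam
        changes[name] = cls(p.mean, 0.0)
    return params.replace(**changes)


class TestSampling:
    def test_zero_sd_draw_returns_the_means(self, baseline):
        degenerate = _zero_sd(baseline)
        rng = np.random.default_rng(1)
        draw = sample_parameters(degenerate, rng)
        for name, p in degenerate.items():
            assert getattr(draw, name).mean == p.mean

    def test_point_mass_probabilities_never_sampled(self, baseline):
        rng = np.random.default_rng(2)
        for _ in range(50):
            draw = sample_parameters(baseline, rng)
            assert draw.p_imaging_short.mean == 1.0
            assert draw.p_imaging_mid.mean == 1.0

    def test_sample_moments_recover_inputs(self, baseline):
        rng = np.random.default_rng(3)
        n = 10_000
        p_success = np.empty(n)
        c_stent = np.empty(n)
        for i in range(n):
            draw = sample_parameters(baseline, rng)
            p_success[i] = draw.p_success.mean
            c_stent[i] = draw.c_stent.mean
        se = baseline.p_success.sd / np.sqrt(n)
        assert abs(p_success.mean() - 0.967) < 3 * se
        assert abs(c_stent.std(ddof=1) - 2612.84) < 0.1 * 2612.84
        assert (p_success <= 1.0).all() and (p_success >= 0.0).all()
        assert (c_stent >= 0.0).all()

    def test_infeasible_moments_fail_before_the_run(self, baseline):
        bad = baseline.replace(p_awi=ProbParam(0.008, 0.5))
        with pytest.raises(InfeasibleMomentsError, match="p_awi"):
            fit_distributions(bad)


class TestRunPSA:
    def test_zero_variance_recovers_deterministic_table(self, baseline, specs, disc):
        degenerate = _zero_sd(baseline)
        result = run_psa(degenerate, specs, disc, n=20, seed=0)
        published_overall = {k: v[3] for k, v in PUBLISHED_TABLE.items()}
        for j, name in enumerate(result.scenario_names):
            col = result.totals[:, j]
            assert np.ptp(col) == 0.0
            assert round(col[0]) == published_overall[name]
        summary = summarize_psa(result)
        assert (summary["total_ci_low"] == summary["total_ci_high"]).all()
        s3 = summary.set_index("scenario").loc["Scenario 3"]
        assert round(s3["mean_avoidable"]) == 898

    def test_fixed_seed_is_bit_reproducible(self, baseline, specs, disc):
        a = run_psa(baseline, specs, disc, n=50, seed=7)
        b = run_psa(baseline, specs, disc, n=50, seed=7)
        assert (a.totals == b.totals).all()
        assert (a.avoidable == b.avoidable).all()

    def test_avoidable_is_per_iteration_difference(self, baseline, specs, disc):
        result = run_psa(baseline, specs, disc, n=30, seed=11)
        expected = result.totals[:, :1] - result.totals[:, 1:]
        assert (result.avoidable == expected).all()

    def test_mean_totals_converge_to_deterministic(self, baseline, specs, disc):
        # the expected cost is multilinear in independently sampled inputs, so
        # the Monte-Carlo mean must approach the deterministic value
        result = run_psa(baseline, specs, disc, n=4000, seed=5)
        base_det = total_cost(baseline, disc).total
        col = result.totals[:, 0]
        se = col.std(ddof=1) / np.sqrt(result.n_iterations)
        assert abs(col.mean() - base_det) < 5 * se

    def test_sd_inflation_keeps_means_and_widens_cis(self, baseline, specs, disc):
        plain = run_psa(baseline, specs, disc, n=2000, seed=9)
        inflated = run_psa(baseline, specs, disc, n=2000, seed=9, sd_scale=2.0)
        sp, si = summarize_psa(plain), summarize_psa(inflated)
        for j in range(len(plain.scenario_names)):
            se = inflated.totals[:, j].std(ddof=1) / np.sqrt(2000)
            assert abs(si["mean_total"][j] - sp["mean_total"][j]) < 5 * se
            width_plain = sp["total_ci_high"][j] - sp["total_ci_low"][j]
            width_inflated = si["total_ci_high"][j] - si["total_ci_low"][j]
            assert width_inflated > width_plain

    def test_independent_sampling_mode(self, baseline, specs, disc):
        result = run_psa(baseline, specs, disc, n=2000, seed=13, coupled=False)
        base_det = total_cost(baseline, disc).total
        col = result.totals[:, 0]
        se = col.std(ddof=1) / np.sqrt(2000)
        assert abs(col.mean() - base_det) < 5 * se
        # decoupled draws have noisier avoidable costs than coupled ones
        coupled = run_psa(baseline, specs, disc, n=2000, seed=13)
        assert result.avoidable[:, 0].std() > coupled.avoidable[:, 0].std()

    def test_invalid_seed_type_rejected(self, baseline, specs):
        with pytest.raises(TypeError):
            run_psa(baseline, specs, n=5, seed="not-a-seed")


class TestSummaries:
    @staticmethod
    def _result_with_avoidable(values):
        values = np.asarray(values, dtype=float)
        totals = np.column_stack([values, np.zeros_like(values)])
        return PSAResult(
            n_iterations=len(values),
            seed=0,
            sd_scale=1.0,
            scenario_names=("Baseline", "S"),
            totals=totals,
            avoidable=totals[:, :1] - totals[:, 1:],
        )

    def test_percentile_rule_on_known_sequence(self):
        result = self._result_with_avoidable(np.arange(1, 1001))
        row = summarize_psa(result).set_index("scenario").loc["S"]
        assert row["mean_avoidable"] == pytest.approx(500.5)
        assert row["avoidable_ci_low"] == pytest.approx(25.975)
        assert row["avoidable_ci_high"] == pytest.approx(975.025)

    def test_single_iteration_ci_collapses(self):
        result = self._result_with_avoidable([42.0])
        row = summarize_psa(result).set_index("scenario").loc["S"]
        assert row["avoidable_ci_low"] == row["avoidable_ci_high"] == 42.0

    def test_iterations_table_shape(self, baseline, specs, disc):
        result = run_psa(baseline, specs, disc, n=10, seed=3)
        df = iterations_table(result)
        assert list(df.columns) == ["iteration", "scenario", "total", "avoidable"]
        assert len(df) == 10 * 5
        assert df.loc[df.scenario == "Baseline", "avoidable"].isna().all()
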