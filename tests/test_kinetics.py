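import math

import numpy as np
import pandas as pd
import pytest

from burstlnc.containers import TwoStateKinetics
from burstlnc.kinetics import (
    KineticFit,
    beta_poisson_logpmf,
    bootstrap_ci,
    burst_duration_hours,
    fit_two_state,
    kinetics_filter,
    lrt_kinetics,
    simulate_inference_spread,
)
from burstlnc.synth import sample_beta_poisson

from conftest import beta_poisson_pmf_oracle


class TestLogPmf:
    def test_zero_count_closed_form(self):
        # P(0) = int_0^1 e^-p dp = 1 - e^-1 for unit rates
        lp = beta_poisson_logpmf(0, (1.0, 1.0, 1.0))
        assert lp == pytest.approx(math.log(1.0 - math.exp(-1.0)), abs=1e-10)

    def test_vanishing_synthesis_concentrates_at_zero(self):
        assert math.exp(beta_poisson_logpmf(0, (1.0, 1.0, 1e-12))) == pytest.approx(1.0)

    @pytest.mark.parametrize("kin", [
        (1.0, 9.0, 100.0), (0.3, 4.0, 60.0), (5.0, 0.5, 20.0), (0.05, 2.0, 10.0),
    ])
    def test_normalization(self, kin):
        x = np.arange(0, 400)
        total = np.exp(beta_poisson_logpmf(x, kin)).sum()
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("kin", [
        (1.0, 9.0, 100.0), (0.05, 2.0, 10.0), (100.0, 900.0, 2000.0),
        (0.001, 0.5, 100.0), (2.0, 3.0, 1000.0),
    ])
    def test_agrees_with_integration_oracle(self, kin):
        x = np.unique(np.round(np.linspace(0, max(5, kin[2] * 0.5), 8)).astype(int))
        got = np.exp(beta_poisson_logpmf(x, kin))
        want = beta_poisson_pmf_oracle(x, *kin)
        assert np.max(np.abs(got - want)) < 1e-8

    def test_input_validation(self):
        with pytest.raises(ValueError):
            beta_poisson_logpmf(-1, (1, 1, 1))
        with pytest.raises(ValueError):
            beta_poisson_logpmf(0, (1, -1, 1))


class TestFitTwoState:
    def test_recovers_simulated_kinetics(self):
        truth = TwoStateKinetics(0.5, 5.0, 50.0)
        ok = 0
        n_rep = 10
        for rep in range(n_rep):
            counts = sample_beta_poisson(truth, 2000, seed=100 + rep)
            fit = fit_two_state(counts)
            err = [abs(math.log2(getattr(fit.kinetics, p) / getattr(truth, p)))
                   for p in ("k_on", "k_off", "k_syn")]
            ok += max(err) < 0.5
        assert ok >= 0.9 * n_rep

    def test_always_on_limit_behaves_like_poisson(self):
        # k_on huge, k_off tiny: promoter effectively always on
        counts = sample_beta_poisson(TwoStateKinetics(100.0, 0.01, 20.0), 2000, seed=3)
        fit = fit_two_state(counts)
        assert fit.kinetics.mean == pytest.approx(counts.mean(), rel=0.05)
        # near-Poisson dispersion
        assert counts.var(ddof=1) / counts.mean() == pytest.approx(1.0, abs=0.2)

    def test_all_zero_is_degenerate(self):
        fit = fit_two_state(np.zeros(100))
        assert fit.degenerate and fit.kinetics is None

    def test_too_few_expressing_cells_is_degenerate(self):
        counts = np.zeros(100)
        counts[:4] = 5
        assert fit_two_state(counts).degenerate

    def test_missing_cells_excluded(self):
        counts = np.array([5, 3, 0, 0, 2, 4, 1, 9, 9, 9], dtype=float)
        mask = np.zeros(10, dtype=bool)
        mask[-3:] = True
        fit = fit_two_state(counts, missing_mask=mask)
        assert fit.n_cells == 7 and fit.n_missing == 3


class TestBootstrap:
    def test_same_seed_same_cis(self):
        counts = sample_beta_poisson(TwoStateKinetics(0.5, 5.0, 50.0), 300, seed=1)
        f1 = bootstrap_ci(counts, n_boot=20, seed=9)
        f2 = bootstrap_ci(counts, n_boot=20, seed=9)
        assert f1.ci_low == f2.ci_low and f1.ci_high == f2.ci_high

    def test_truth_inside_ci_for_most_genes(self):
        truth = TwoStateKinetics(0.5, 5.0, 50.0)
        inside = 0
        n_rep = 5
        for rep in range(n_rep):
            counts = sample_beta_poisson(truth, 500, seed=200 + rep)
            fit = bootstrap_ci(counts, n_boot=60, seed=rep)
            inside += (fit.ci_low["k_on"] <= truth.k_on <= fit.ci_high["k_on"])
        assert inside >= n_rep - 1

    def test_identical_counts_give_zero_spread_for_the_mean(self):
        counts = np.full(50, 4.0)
        fit = bootstrap_ci(counts, n_boot=20, seed=0)
        means = fit.bootstrap["k_syn"] * fit.bootstrap["k_on"] / (
            fit.bootstrap["k_on"] + fit.bootstrap["k_off"]
        )
        assert means.std() == pytest.approx(0.0, abs=1e-2)


class TestKineticsFilter:
    def _fit(self, k_on=1.0, k_off=10.0, k_syn=50.0, mean_umi=3.0, ci_ratio=4.0):
        fit = KineticFit(gene="g", allele="CAST",
                         kinetics=TwoStateKinetics(k_on, k_off, k_syn),
                         mean_umi=mean_umi, n_cells=100, converged=True)
        for par in ("k_on", "burst_size"):
            base = fit.kinetics.k_on if par == "k_on" else fit.kinetics.burst_size
            fit.ci_low[par] = base / math.sqrt(ci_ratio)
            fit.ci_high[par] = base * math.sqrt(ci_ratio)
        fit.bootstrap = pd.DataFrame()
        return fit

    def test_small_burst_size_fails(self):
        ok, reasons = kinetics_filter(self._fit(k_syn=1.0, k_off=10.0))  # size 0.1
        assert not ok and "size" in reasons

    def test_wide_ci_fails(self):
        ok, reasons = kinetics_filter(self._fit(ci_ratio=40.0))  # 40 > 10^1.5
        assert not ok and any(r.startswith("ci_width") for r in reasons)

    def test_all_within_bounds_passes(self):
        ok, reasons = kinetics_filter(self._fit(k_on=1.0, k_off=10.0, k_syn=50.0))
        assert ok and reasons == []

    @pytest.mark.parametrize("kw,reason", [
        (dict(k_on=0.005), "frequency"),
        (dict(mean_umi=0.005), "mean_expression"),
    ])
    def test_other_bounds(self, kw, reason):
        ok, reasons = kinetics_filter(self._fit(**kw))
        assert not ok and reason in reasons


class TestLrt:
    def test_identical_samples_give_zero_lambda(self):
        counts = sample_beta_poisson(TwoStateKinetics(1.0, 10.0, 60.0), 500, seed=5)
        res = lrt_kinetics(counts, counts.copy(), "frequency")
        assert res.lambda_lr == pytest.approx(0.0, abs=0.2)
        assert not res.significant_one_sided

    def test_lambda_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for rep in range(3):
            a = sample_beta_poisson(TwoStateKinetics(0.8, 8.0, 40.0), 200,
                                    seed=int(rng.integers(2**31)))
            b = sample_beta_poisson(TwoStateKinetics(1.5, 12.0, 80.0), 200,
                                    seed=int(rng.integers(2**31)))
            res = lrt_kinetics(a, b, "size")
            assert res.lambda_lr >= 0.0

    def test_detects_doubled_frequency(self):
        a = sample_beta_poisson(TwoStateKinetics(1.0, 10.0, 60.0), 1000, seed=11)
        b = sample_beta_poisson(TwoStateKinetics(2.0, 10.0, 60.0), 1000, seed=12)
        res = lrt_kinetics(a, b, "frequency")
        assert res.significant_one_sided
        assert res.theta_hat == pytest.approx(1.0, abs=0.5)

    def test_insufficient_sample_rejected(self):
        with pytest.raises(ValueError):
            lrt_kinetics(np.zeros(10), np.ones(10), "frequency")


class TestInferenceSpread:
    def test_frequency_mode_doubles_frequency_only(self):
        ref = TwoStateKinetics(1.0, 10.0, 60.0)
        cloud = simulate_inference_spread(ref, 2.0, "frequency", 500, n_sim=15, seed=0)
        assert cloud["burst_frequency"].median() == pytest.approx(2.0, rel=0.3)
        assert cloud["burst_size"].median() == pytest.approx(6.0, rel=0.3)

    def test_identity_perturbation_centers_on_reference(self):
        ref = TwoStateKinetics(1.0, 10.0, 60.0)
        cloud = simulate_inference_spread(ref, 1.0, "size", 500, n_sim=15, seed=1)
        assert cloud["burst_size"].median() == pytest.approx(6.0, rel=0.3)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            simulate_inference_spread(TwoStateKinetics(1, 1, 1), 2.0, "both", 10)


class TestBurstDuration:
    def test_unit_case(self):
        assert burst_duration_hours(1.0, math.log(2.0)) == pytest.approx(1.0)

    def test_worked_example(self):
        # lambda = ln2/4 = 0.1733 per hour; 1/(0.25 * 0.1733) ~ 23.08 h
        assert burst_duration_hours(0.25, 4.0) == pytest.approx(23.08, abs=0.01)

    def test_proportional_in_half_life(self):
        assert burst_duration_hours(0.5, 8.0) == pytest.approx(
            2.0 * burst_duration_hours(0.5, 4.0)
        )

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            burst_duration_hours(0.0, 1.0)
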