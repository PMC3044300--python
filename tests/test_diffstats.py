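"""Paired t-test, time x group regression, contrasts, and batch analysis."""

import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hdxstat.diffstats import (
    ModelSpec,
    adjust_pvalues,
    analyze_dataset,
    fit_linear_model,
    group_contrast,
    paired_differences,
    paired_t_test,
)
from hdxstat.exceptions import (
    DesignRankError,
    EmptyDatasetError,
    InsufficientDataError,
    PairingError,
)
from hdxstat.peaklist import ExchangeDataset, build_dataset
from hdxstat.simulate import PeptideSpec, SyntheticSpec, simulate_dataset, two_state_spec
from hdxstat.uptake import UptakeObservation

from .oracles import normal_equations_ols, textbook_paired_t


def obs(state, t, rep, value):
    return UptakeObservation(
        peptide_id="p", state=state, time_s=float(t), replicate=rep,
        centroid_mz=500.0, charge=1, deuteration_pct=float(value),
    )


class TestPairedDifferences:
    def test_identical_series_give_zeros(self):
        a = [obs("apo", t, 1, 10 + t) for t in (600, 1200, 1800)]
        b = [obs("lig", t, 1, 10 + t) for t in (600, 1200, 1800)]
        np.testing.assert_array_equal(paired_differences(a, b), [0.0, 0.0, 0.0])

    def test_constant_shift(self):
        a = [obs("apo", t, 1, 10 + t) for t in (600, 1200, 1800)]
        b = [obs("lig", t, 1, 10.3 + t) for t in (600, 1200, 1800)]
        np.testing.assert_allclose(paired_differences(a, b), [0.3, 0.3, 0.3])

    def test_replicates_averaged_first(self):
        # 2 replicates x 3 timepoints x 2 states, worked by hand:
        # cell means a = (1.5, 3.5, 5.5); b = (2.5, 5.5, 8.5); d = (1, 2, 3)
        a_vals = {600: [1, 2], 1200: [3, 4], 1800: [5, 6]}
        b_vals = {600: [2, 3], 1200: [5, 6], 1800: [8, 9]}
        a = [obs("apo", t, r + 1, v) for t, vs in a_vals.items() for r, v in enumerate(vs)]
        b = [obs("lig", t, r + 1, v) for t, vs in b_vals.items() for r, v in enumerate(vs)]
        np.testing.assert_allclose(paired_differences(a, b), [1.0, 2.0, 3.0])

    def test_disjoint_timepoints_error(self):
        a = [obs("apo", 600, 1, 1.0), obs("apo", 1200, 1, 2.0)]
        b = [obs("lig", 1800, 1, 1.0), obs("lig", 2400, 1, 2.0)]
        with pytest.raises(PairingError):
            paired_differences(a, b)

    def test_single_timepoint_insufficient(self):
        a = [obs("apo", 600, 1, 1.0)]
        b = [obs("lig", 600, 1, 2.0)]
        with pytest.raises(InsufficientDataError):
            paired_differences(a, b)


class TestPairedTTest:
    def test_null_self_comparison(self):
        r = paired_t_test(np.zeros(3))
        assert r.estimate == 0.0 and r.p_value == 1.0
        assert (r.ci_low, r.ci_high) == (0.0, 0.0)

    def test_closed_form_example(self):
        r = paired_t_test(np.array([1.0, 2.0, 3.0]))
        assert r.estimate == pytest.approx(2.0)
        assert r.df == 2
        assert r.p_value == pytest.approx(0.07418, abs=5e-5)
        half = 4.302653 * (1.0 / np.sqrt(3))
        assert r.ci_low == pytest.approx(2 - half, rel=1e-5)
        assert r.ci_high == pytest.approx(2 + half, rel=1e-5)

    def test_degenerate_nonzero_constant(self, caplog):
        with caplog.at_level(logging.WARNING):
            r = paired_t_test(np.array([0.5, 0.5, 0.5]))
        assert r.p_value == 0.0 and r.estimate == 0.5

    def test_matches_textbook_formulas(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 11))
            d = rng.normal(size=n)
            r = paired_t_test(d)
            mean, _, df, p, lo, hi = textbook_paired_t(d)
            assert r.estimate == pytest.approx(mean, abs=1e-10)
            assert r.df == df
            assert r.p_value == pytest.approx(p, abs=1e-10)
            assert r.ci_low == pytest.approx(lo, abs=1e-10)
            assert r.ci_high == pytest.approx(hi, abs=1e-10)


def make_observations(rng, n_times=4, reps=2, beta=(1.0, 0.5, 2.0, 0.0), noise=0.0):
    """Observations generated from the linear model itself."""
    out = []
    for g, state in ((0, "apo"), (1, "lig")):
        for t in np.linspace(600, 2400, n_times):
            for r in range(reps):
                y = beta[0] + beta[1] * t + beta[2] * g + beta[3] * t * g
                y += noise * rng.normal()
                out.append(obs(state, t, r + 1, y))
    return out


class TestLinearModel:
    def test_noiseless_exact_recovery(self, rng):
        spec = ModelSpec(include_interaction=False)
        observations = make_observations(rng, beta=(1.0, 0.5, 2.0, 0.0))
        fit = fit_linear_model(observations, spec, "apo", "lig")
        assert fit.beta0 == pytest.approx(1.0, abs=1e-8)
        assert fit.beta_T == pytest.approx(0.5, abs=1e-10)
        assert fit.beta_G == pytest.approx(2.0, abs=1e-8)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self, rng):
        spec = ModelSpec()
        for _ in range(20):
            observations = make_observations(
                rng, n_times=int(rng.integers(3, 6)), reps=int(rng.integers(1, 4)),
                beta=tuple(rng.normal(size=4)), noise=1.0,
            )
            fit = fit_linear_model(observations, spec, "apo", "lig")
            times = np.array([o.time_s for o in observations])
            groups = np.array([0.0 if o.state == "apo" else 1.0 for o in observations])
            y = np.array([o.deuteration_pct for o in observations])
            X = np.column_stack([np.ones_like(times), times, groups, times * groups])
            beta, cov, sigma2, df = normal_equations_ols(X, y)
            np.testing.assert_allclose(fit.params, beta, rtol=1e-8)
            np.testing.assert_allclose(fit.cov, cov, rtol=1e-6, atol=1e-12)
            assert fit.sigma2 == pytest.approx(sigma2, rel=1e-8)
            assert fit.df_resid == df

    def test_single_timepoint_design_is_rank_deficient(self):
        observations = [obs("apo", 600, r, v) for r, v in enumerate((1, 2, 3, 4, 5))]
        observations += [obs("lig", 600, r, v) for r, v in enumerate((2, 3, 4, 5, 6))]
        with pytest.raises((DesignRankError, InsufficientDataError)):
            fit_linear_model(observations, ModelSpec(), "apo", "lig")

    def test_log10_with_zero_time_instructs_min_time(self, rng):
        observations = make_observations(rng) + [obs("apo", 0.0, 1, 1.0), obs("lig", 0.0, 1, 1.0)]
        with pytest.raises(ValueError, match="min_time_s"):
            fit_linear_model(observations, ModelSpec(time_transform="log10"), "apo", "lig")

    def test_coefficient_recovery_is_unbiased(self, rng):
        """Parameter recovery: estimates average out to the truth."""
        truth = (5.0, 0.01, 1.5, 0.002)
        estimates = []
        for _ in range(300):
            observations = make_observations(rng, beta=truth, noise=1.0)
            estimates.append(fit_linear_model(observations, ModelSpec(), "apo", "lig").params)
        mean_est = np.mean(estimates, axis=0)
        # Monte-Carlo error bound: 4 sd of each coefficient's mean
        sds = np.std(estimates, axis=0) / np.sqrt(300)
        np.testing.assert_array_less(np.abs(mean_est - np.array(truth)), 4 * sds + 1e-12)


class TestGroupContrast:
    def test_no_group_effect(self, rng):
        observations = make_observations(rng, beta=(1.0, 0.5, 0.0, 0.0))
        fit = fit_linear_model(observations, ModelSpec(), "apo", "lig")
        times = np.array([o.time_s for o in observations])
        r = group_contrast(fit, ModelSpec(), times)
        assert r.estimate == pytest.approx(0.0, abs=1e-9)
        assert r.p_value >= 0.99

    def test_interaction_off_ignores_eval_time(self, rng):
        observations = make_observations(rng, beta=(1.0, 0.5, 0.3, 0.0))
        times = np.array([o.time_s for o in observations])
        for eval_time in ("mean", 600.0, 2400.0):
            spec = ModelSpec(include_interaction=False, eval_time=eval_time)
            fit = fit_linear_model(observations, spec, "apo", "lig")
            r = group_contrast(fit, spec, times)
            assert r.estimate == pytest.approx(0.3, abs=1e-8)

    def test_extrapolation_warns_but_succeeds(self, rng, caplog):
        observations = make_observations(rng, noise=0.1)
        spec = ModelSpec(eval_time=10_000.0)
        fit = fit_linear_model(observations, spec, "apo", "lig")
        times = np.array([o.time_s for o in observations])
        with caplog.at_level(logging.WARNING):
            r = group_contrast(fit, spec, times)
        assert "extrapolat" in caplog.text
        assert 0 <= r.p_value <= 1

    def test_balanced_design_equals_paired_t(self, rng):
        """On a balanced complete design the contrast at mean time equals
        the mean paired difference (OLS identity)."""
        for seed in range(10):
            sim = simulate_dataset(two_state_spec(seed=seed, rate_ratio=1.2))
            ds = build_dataset(sim.peaklists, "apo", "ligand")
            results = analyze_dataset(ds, ModelSpec(min_time_s=600.0))
            by_method = {r.method: r for r in results}
            assert by_method["regression"].estimate == pytest.approx(
                by_method["paired_t"].estimate, abs=1e-8
            )


class TestAdjustPvalues:
    def _result(self, p, i=0):
        from hdxstat.diffstats import DifferentialResult

        return DifferentialResult(
            peptide_id=f"p{i}", method="paired_t", estimate=0.0, ci_low=-1.0,
            ci_high=1.0, p_value=p, df=3, n=4, response="percentD",
        )

    def test_single_result_unchanged(self):
        (r,) = adjust_pvalues([self._result(0.03)])
        assert r.adjusted_p == pytest.approx(0.03)

    def test_bh_step_up_hand_computed(self):
        results = [self._result(p, i) for i, p in enumerate((0.01, 0.02, 0.03, 0.04))]
        adjusted = adjust_pvalues(results)
        assert [r.adjusted_p for r in adjusted] == pytest.approx([0.04] * 4)

    @given(pvals=st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_adjusted_never_below_raw(self, pvals):
        results = [self._result(p, i) for i, p in enumerate(pvals)]
        for r in adjust_pvalues(results):
            assert r.adjusted_p >= r.p_value - 1e-12

    def test_none_copies_raw(self):
        (r,) = adjust_pvalues([self._result(0.2)], method="none")
        assert r.adjusted_p == 0.2


class TestAnalyzeDataset:
    def test_result_counting(self, two_peptide_dataset):
        results = analyze_dataset(two_peptide_dataset, ModelSpec(response="mz"))
        assert len(results) == 4  # 2 peptides x 2 methods

    def test_empty_dataset_error(self):
        with pytest.raises(EmptyDatasetError):
            analyze_dataset(ExchangeDataset("apo", "lig", {}))

    def test_failing_peptide_is_isolated(self, caplog):
        spec = two_state_spec(seed=9, n_peptides=2)
        sim = simulate_dataset(spec)
        # strip all but one timepoint from pep02: insufficient for any method
        lists = [
            pl for pl in sim.peaklists
            if pl.peptide_id != "pep02" or pl.time_s in (None, 600.0)
        ]
        ds = build_dataset(lists, "apo", "ligand")
        with caplog.at_level(logging.WARNING):
            results = analyze_dataset(ds, ModelSpec())
        assert {r.peptide_id for r in results} == {"pep01"}
        assert "pep02" in caplog.text

    def test_shifted_peptide_attains_smallest_pvalue(self):
        """One truly shifted peptide among 10 nulls wins the p-value race
        nearly always when the effect is far above the noise floor.

        The sampling window is chosen where the between-state difference is
        nearly constant over time: the paired t treats time-variation of
        the difference as noise, so a window where the difference grows
        steeply would cap its attainable significance no matter how large
        the effect (a real limitation, exercised elsewhere).
        """
        wins = {"paired_t": 0, "regression": 0}
        n_reps = 200
        master = np.random.default_rng(77)
        window = (1800.0, 1980.0, 2160.0, 2340.0, 2520.0, 2700.0)
        for _ in range(n_reps):
            seed = int(master.integers(2**31 - 1))
            peptides = tuple(
                PeptideSpec(
                    peptide_id=f"pep{i:02d}", base_mz=450.0 + 40 * i, charge=1,
                    n_exchangeable=8, rate_a=5e-5,
                    rate_b=5e-5 * (1.6 if i == 0 else 1.0),
                )
                for i in range(11)
            )
            sim = simulate_dataset(SyntheticSpec(peptides=peptides, timepoints=window, seed=seed))
            ds = build_dataset(sim.peaklists, "apo", "ligand")
            results = analyze_dataset(ds, ModelSpec(min_time_s=600.0))
            for method in wins:
                sub = [r for r in results if r.method == method]
                best = min(sub, key=lambda r: r.p_value)
                if best.peptide_id == "pep00":
                    wins[method] += 1
        for method, w in wins.items():
            assert w / n_reps >= 0.95, f"{method}: {w}/{n_reps}"
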