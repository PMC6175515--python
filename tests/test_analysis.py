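"""Statistical pipeline: regressions, t-test, R-squared, summaries."""

import numpy as np
import pandas as pd
import pytest

from flushrisk import (
    LogisticFit,
    SeparationError,
    fit_fate_logistic,
    fit_ordinal,
    generate_dataset,
    linreg_r2,
    predicted_fate_curve,
    preset,
    summarize,
    two_sample_t,
)
from flushrisk.synthetic import SyntheticConfig


def _records(dists, species="sandpiper", cats=None, fates=None):
    n = len(dists)
    return pd.DataFrame(
        {
            "nest_id": [f"n{i}" for i in range(n)],
            "species": species if isinstance(species, (list, np.ndarray, pd.Series)) else [species] * n,
            "flush_distance_m": dists,
            "defence_category": cats if cats is not None else [1] * n,
            "fate": fates if fates is not None else ["depredated"] * n,
        }
    )


def _moment_matched(values, mean, sd):
    """Rescale a sample to the exact target mean and (n-1) SD."""
    v = np.asarray(values, dtype=float)
    z = (v - v.mean()) / v.std(ddof=1)
    return z * sd + mean


class TestTwoSampleT:
    def test_identical_groups_give_zero(self):
        d = np.r_[np.arange(10.0), np.arange(10.0)]
        sp = ["sandpiper"] * 10 + ["phalarope"] * 10
        res = two_sample_t(_records(d, species=sp))
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_study_moments_reproduce_hand_computed_t(self, rng):
        """Groups built to the field moments: pooled t from the hand formula."""
        n1, n2 = 62, 38
        m1, s1, m2, s2 = 15.3, 18.8, 13.8, 19.0
        a = _moment_matched(rng.normal(size=n1), m1, s1)
        b = _moment_matched(rng.normal(size=n2), m2, s2)
        sp = ["sandpiper"] * n1 + ["phalarope"] * n2
        res = two_sample_t(_records(np.r_[a, b], species=sp))
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        t_hand = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-9)
        assert res.t_statistic == pytest.approx(0.38, abs=0.01)
        assert res.degrees_of_freedom == 98

    def test_label_swap_negates_t(self, rng):
        d = rng.random(30) * 20
        sp = ["sandpiper"] * 15 + ["phalarope"] * 15
        res1 = two_sample_t(_records(d, species=sp))
        res2 = two_sample_t(_records(d, species=sp[::-1]))
        assert res1.t_statistic == pytest.approx(-res2.t_statistic)
        assert res1.p_value == pytest.approx(res2.p_value)

    def test_welch_variant_differs_in_df(self, rng):
        d = np.r_[rng.random(20), 10 * rng.random(10)]
        sp = ["sandpiper"] * 20 + ["phalarope"] * 10
        res = two_sample_t(_records(d, species=sp), variant="welch")
        assert res.degrees_of_freedom < 28

    def test_tiny_group_rejected(self):
        df = _records([1.0, 2.0, 3.0], species=["sandpiper", "sandpiper", "phalarope"])
        with pytest.raises(ValueError):
            two_sample_t(df)


class TestLinregR2:
    def test_exact_line(self):
        x = np.arange(10.0)
        assert linreg_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        assert linreg_r2(rng.random(5000), rng.random(5000)) < 0.01

    def test_hand_worked_small_set(self):
        # OLS by hand: Sxy=1, Sxx=2, Syy=2 -> R^2 = 1/4
        assert linreg_r2([0, 1, 2], [1, 3, 2]) == pytest.approx(0.25)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            linreg_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFateLogistic:
    def test_recovers_generating_coefficients(self):
        cfg = preset("paper_like")
        df = generate_dataset(cfg, n_per_species={"sandpiper": 20000, "phalarope": 10000}, seed=5)
        fit = fit_fate_logistic(df)
        gen = cfg.fate_model
        for got, true, se in [
            (fit.intercept, gen.intercept, fit.standard_errors["intercept"]),
            (fit.beta_flush, gen.beta_flush, fit.standard_errors["flush"]),
            (fit.beta_flush_sq, gen.beta_flush_sq, fit.standard_errors["flush_sq"]),
        ]:
            assert abs(got - true) <= 2 * se

    def test_unknown_fates_excluded(self, paper_like_dataset):
        fit = fit_fate_logistic(paper_like_dataset)
        n_known = (paper_like_dataset["fate"] != "unknown").sum()
        assert fit.n == n_known

    def test_single_class_outcome_rejected(self):
        df = _records(np.arange(20.0), fates=["hatched"] * 20)
        with pytest.raises(SeparationError):
            fit_fate_logistic(df)

    def test_vertex_is_predation_peak(self):
        fit = LogisticFit(
            intercept=0.5, beta_flush=-0.141, beta_flush_sq=0.002,
            standard_errors={}, wald_p_values={}, log_likelihood=0.0, converged=True, n=100,
        )
        assert fit.predation_peak == pytest.approx(35.25)


class TestPredictedFateCurve:
    def test_printed_coefficients_vertex(self):
        fit = LogisticFit(
            intercept=0.0, beta_flush=-0.141, beta_flush_sq=0.002,
            standard_errors={}, wald_p_values={}, log_likelihood=0.0, converged=True, n=100,
        )
        curve, peak = predicted_fate_curve(fit, peak_range=(0.0, 100.0))
        assert peak == pytest.approx(35.25, abs=1e-9)
        assert 20.0 <= peak <= 70.0
        np.testing.assert_allclose(curve["p_predation"], 1.0 - curve["p_hatch"])

    def test_zero_linear_term_peaks_at_origin(self):
        fit = LogisticFit(
            intercept=0.0, beta_flush=0.0, beta_flush_sq=0.01,
            standard_errors={}, wald_p_values={}, log_likelihood=0.0, converged=True, n=100,
        )
        _, peak = predicted_fate_curve(fit, peak_range=(0.0, 100.0))
        assert peak == 0.0


class TestOrdinal:
    def test_recovers_generating_coefficients(self):
        cfg = preset("paper_like")
        df = generate_dataset(cfg, n_per_species={"sandpiper": 15000, "phalarope": 15000}, seed=6)
        fit = fit_ordinal(df)
        om = cfg.ordinal_model
        assert abs(fit.coefficients["species_sandpiper"] - om.species_coef) <= 2 * fit.standard_errors["species_sandpiper"]
        assert abs(fit.coefficients["flush_distance_m"] - om.flush_coef) <= 2 * fit.standard_errors["flush_distance_m"]
        for got, true in zip(fit.cutpoints, om.cutpoints):
            assert got == pytest.approx(true, abs=0.1)

    def test_term_chi_squares_nonnegative_with_df1(self, paper_like_dataset):
        fit = fit_ordinal(paper_like_dataset)
        for stat, df, p in fit.term_chi_squares.values():
            assert stat >= 0.0
            assert df == 1
            assert 0.0 <= p <= 1.0

    def test_intercept_only_recovers_marginal_proportions(self):
        # single species, no flush effect in generator: cell probabilities
        # from the fitted cutpoints must match observed margins
        cfg = SyntheticConfig(
            n_per_species={"sandpiper": 4000, "phalarope": 0},
            seed=7,
        )
        df = generate_dataset(cfg)
        df["flush_distance_m"] = 10.0  # constant: flush term dropped from fit
        fit = fit_ordinal(df)
        from scipy.special import expit

        cum = np.r_[expit(np.array(fit.cutpoints)), 1.0]
        fitted = np.diff(np.r_[0.0, cum])
        observed = df["defence_category"].value_counts(normalize=True).reindex([1, 2, 3, 4]).fillna(0)
        np.testing.assert_allclose(fitted, observed.to_numpy(), atol=5e-3)

    def test_single_category_rejected(self):
        df = _records(np.arange(10.0), cats=[2] * 10)
        with pytest.raises(ValueError):
            fit_ordinal(df)


class TestSummarize:
    def test_single_record(self):
        df = _records([10.0], cats=[1], fates=["hatched"])
        s = summarize(df)
        assert s.per_species_mean["sandpiper"] == 10.0
        assert s.category_proportions["sandpiper"][1] == 1.0
        assert s.hatch_success["sandpiper"] == 1.0

    def test_boundary_value_falls_in_middle_bin(self):
        s = summarize(_records([5.0] * 4))
        assert s.bin_proportions == {"below": 0.0, "mid": 1.0, "above": 0.0}

    def test_bins_partition(self, paper_like_dataset):
        s = summarize(paper_like_dataset)
        assert sum(s.bin_proportions.values()) == pytest.approx(1.0)

    def test_sample_moments_track_generator(self):
        cfg = preset("paper_like")
        df = generate_dataset(cfg, n_per_species={"sandpiper": 40000, "phalarope": 40000}, seed=8)
        s = summarize(df)
        for sp, target_mean, target_sd in [("sandpiper", 15.3, 18.8), ("phalarope", 13.8, 19.0)]:
            se = target_sd / np.sqrt(s.per_species_n[sp])
            assert abs(s.per_species_mean[sp] - target_mean) <= 3 * se

    def test_hatch_success_counts_unknown_in_denominator(self):
        df = _records([1.0, 2.0, 3.0, 4.0], fates=["hatched", "depredated", "unknown", "unknown"])
        assert summarize(df).hatch_success["sandpiper"] == 0.25

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(_records([]))


class TestPipelineOnStudyShapedData:
    """End-to-end pipeline run on a synthetic stand-in shaped like the field
    study (species sizes, flush moments, defence and fate models)."""

    def test_full_pipeline_runs_and_is_coherent(self, paper_like_dataset):
        from flushrisk import dip_test

        df = paper_like_dataset
        s = summarize(df)
        assert s.per_species_n == {"sandpiper": 62, "phalarope": 38}
        t = two_sample_t(df)
        assert t.degrees_of_freedom == 98
        dip = dip_test(df["flush_distance_m"].to_numpy(), n_null_samples=999, seed=0)
        assert 0.005 <= dip.statistic <= 0.25
        ordinal = fit_ordinal(df)
        assert ordinal.coefficients["species_sandpiper"] > 0  # sandpipers escalate more
        fate = fit_fate_logistic(df)
        assert fate.n == (df["fate"] != "unknown").sum()
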