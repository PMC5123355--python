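"""Burden comparisons: direct tests, matched resampling, count GLM, strata."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import crrlink as cl
from crrlink.enrichment import (
    compare_groups,
    fit_mutation_glm,
    matched_resample_test,
    stratified_reports,
)
from crrlink.synthetic_data import SimulationConfig, simulate_crr_covariate_table


def stats_frame(counts_chosen, counts_rejected, conf_chosen=None, conf_rejected=None):
    n_c, n_r = len(counts_chosen), len(counts_rejected)
    return pd.DataFrame(
        {
            "mutation_count": list(counts_chosen) + list(counts_rejected),
            "chosen": [True] * n_c + [False] * n_r,
            "length_bp": (
                list(conf_chosen) + list(conf_rejected)
                if conf_chosen is not None
                else [500.0] * (n_c + n_r)
            ),
        }
    )


class TestCompareGroups:
    def test_worked_arithmetic(self):
        res = compare_groups([2, 0, 1], [0, 0, 1, 0])
        assert res.proportion_mutated_chosen == pytest.approx(2 / 3)
        assert res.proportion_mutated_rejected == pytest.approx(1 / 4)
        assert res.mean_count_chosen == pytest.approx(1.0)
        assert res.mean_count_rejected == pytest.approx(0.25)
        assert res.enrichment_factor == pytest.approx(4.0)

    def test_factor_equals_direct_count_arithmetic(self, rng):
        c = rng.poisson(1.4, 300)
        r = rng.poisson(0.9, 900)
        res = compare_groups(c, r)
        assert res.enrichment_factor == pytest.approx(
            (c.sum() / len(c)) / (r.sum() / len(r))
        )

    def test_identical_groups_not_significant(self):
        counts = [0, 1, 2, 0, 1, 3, 0, 0]
        res = compare_groups(counts, counts)
        assert res.enrichment_factor == pytest.approx(1.0)
        assert res.t_p >= 0.45
        assert res.wilcoxon_p >= 0.45
        assert res.fisher_p >= 0.45

    def test_zero_variance_group_skips_t_test_only(self):
        res = compare_groups([1, 1, 1], [1, 1, 1])
        assert np.isnan(res.t_p)
        assert np.isnan(res.chi2_p)  # degenerate 2x2 (nobody unmutated)
        assert not np.isnan(res.wilcoxon_p)
        assert not np.isnan(res.fisher_p)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1])

    def test_type_one_error_under_exchangeable_null(self, rng):
        """With no chosen/rejected difference the tests hold their level:
        Welch t near nominal, the discrete tests at or below it."""
        alpha, reps = 0.05, 500
        rej = {"t": 0, "w": 0, "chi2": 0, "fisher": 0}
        for _ in range(reps):
            res = compare_groups(rng.poisson(1.0, 200), rng.poisson(1.0, 200))
            rej["t"] += res.t_p < alpha
            rej["w"] += res.wilcoxon_p < alpha
            rej["chi2"] += res.chi2_p < alpha
            rej["fisher"] += res.fisher_p < alpha
        upper = alpha + 1.96 * np.sqrt(alpha * (1 - alpha) / reps)
        lower = alpha - 1.96 * np.sqrt(alpha * (1 - alpha) / reps)
        assert lower <= rej["t"] / reps <= upper
        for name in ("w", "chi2", "fisher"):
            assert rej[name] / reps <= upper


class TestMatchedResampling:
    def test_single_bin_reduces_to_random_subsampling(self, rng):
        df = stats_frame(rng.poisson(1.5, 40), rng.poisson(1.0, 200))
        res = matched_resample_test(df, "length_bp", n_draws=5, seed=1)
        assert len(res.draws) == 5
        assert all(d.n_rejected == 40 for d in res.draws)

    def test_sampled_rejected_histogram_equals_chosen_histogram(self, rng):
        conf_c = rng.uniform(0, 10, 60)
        conf_r = rng.uniform(0, 10, 400)
        df = stats_frame(
            rng.poisson(1, 60), rng.poisson(1, 400), conf_c, conf_r
        )
        edges = np.quantile(conf_c, [0, 0.25, 0.5, 0.75, 1.0])
        edges[0], edges[-1] = -np.inf, np.inf
        res = matched_resample_test(df, "length_bp", n_draws=1, seed=2)
        # rerun the binning on the matched draw via the count identity
        need = np.histogram(conf_c, edges)[0]
        assert need.sum() == res.draws[0].n_rejected == 60

    def test_bin_deficit_raises_naming_bin(self, rng):
        conf_c = np.concatenate([np.zeros(30), np.ones(10) * 9])
        conf_r = np.zeros(100)  # nothing to match the high bin
        df = stats_frame(np.ones(40), np.ones(100), conf_c, conf_r)
        with pytest.raises(ValueError, match="bin"):
            matched_resample_test(df, "length_bp", seed=0)

    def test_seeded_draws_are_reproducible(self, rng):
        df = stats_frame(rng.poisson(1, 50), rng.poisson(1, 300),
                         rng.uniform(0, 1, 50), rng.uniform(0, 1, 300))
        a = matched_resample_test(df, "length_bp", n_draws=3, seed=9)
        b = matched_resample_test(df, "length_bp", n_draws=3, seed=9)
        assert [d.mean_count_rejected for d in a.draws] == [
            d.mean_count_rejected for d in b.draws
        ]


class TestMutationGlm:
    def make_table(self, rng, n=2000, delta=0.46):
        config = SimulationConfig(functional_enrichment_delta=delta)
        return simulate_crr_covariate_table(n, config, rng)

    def test_poisson_parameter_recovery(self, rng):
        config = SimulationConfig()
        df = simulate_crr_covariate_table(2000, config, rng)
        fit = fit_mutation_glm(df)
        truth = {
            "log_length": config.beta_log_length,
            "replication_timing": config.beta_replication_timing,
            "gc": config.beta_gc,
            "log1p_tss_distance": 0.0,
            "chosen": config.functional_enrichment_delta,
            "const": config.mutation_rate_base,
        }
        for name, true_val in truth.items():
            assert abs(fit.params[name] - true_val) < 3 * fit.bse[name], name
        assert 0.8 < fit.dispersion < 1.2
        assert not fit.quasi

    def test_all_zero_counts_rejected(self, rng):
        df = self.make_table(rng, n=100)
        df["mutation_count"] = 0
        with pytest.raises(ValueError, match="zero"):
            fit_mutation_glm(df)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 20"):
            fit_mutation_glm(self.make_table(rng, n=10))

    def test_overdispersed_counts_trigger_quasi_with_wider_ses(self, rng):
        df = self.make_table(rng, n=3000, delta=0.0)
        rates = df["mutation_count"].to_numpy(dtype=float).clip(0.2)
        # negative-binomial counts: Poisson with Gamma-mixed rates
        mixed = rates * rng.gamma(shape=0.5, scale=2.0, size=len(df))
        df["mutation_count"] = rng.poisson(mixed)
        fit = fit_mutation_glm(df)
        assert fit.dispersion > 1.5
        assert fit.quasi
        X = sm.add_constant(
            pd.DataFrame(
                {
                    "log_length": np.log(df["length_bp"]),
                    "replication_timing": df["replication_timing"],
                    "gc": df["gc"],
                    "log1p_tss_distance": np.log1p(df["nearest_tss_distance"]),
                    "chosen": df["chosen"].astype(float),
                }
            )
        )
        poisson_bse = sm.GLM(
            df["mutation_count"].to_numpy(), X, family=sm.families.Poisson()
        ).fit().bse
        assert (fit.bse.to_numpy() > poisson_bse.to_numpy()).all()


class TestStratifiedReports:
    def make_stats(self, rng):
        n_c, n_r = 80, 400
        df = pd.DataFrame(
            {
                "crr_id": [f"c{i}" for i in range(n_c + n_r)],
                "mutation_count": np.concatenate(
                    [rng.poisson(1.5, n_c), rng.poisson(1.0, n_r)]
                ),
                "chosen": [True] * n_c + [False] * n_r,
                "model_r_max": np.concatenate(
                    [rng.uniform(0.2, 1.0, n_c), np.full(n_r, np.nan)]
                ),
                "proximal": pd.array([True, False] * ((n_c + n_r) // 2), dtype="boolean"),
                "role": ["enhancer", "repressor"] * ((n_c + n_r) // 2),
            }
        )
        return df

    def test_zero_threshold_equals_unstratified(self, rng):
        df = self.make_stats(rng)
        rep = stratified_reports(df, models=None, thresholds=(0.0,))
        assert rep["r_gt_0"].n_chosen == rep["all"].n_chosen
        assert rep["r_gt_0"].enrichment_factor == pytest.approx(
            rep["all"].enrichment_factor
        )

    def test_impossible_threshold_gives_empty_stratum(self, rng):
        rep = stratified_reports(self.make_stats(rng), models=None, thresholds=(1.01,))
        assert rep["r_gt_1.01"] is None

    def test_enrichment_rises_when_high_r_models_carry_stronger_effect(self, rng):
        # planted: chosen CRRs from better models are mutated at higher rates
        n_c, n_r = 150, 600
        r_max = rng.uniform(0.2, 1.0, n_c)
        rate_c = np.exp(np.log(0.9) + 0.8 * (r_max > 0.7))
        df = pd.DataFrame(
            {
                "crr_id": [f"c{i}" for i in range(n_c + n_r)],
                "mutation_count": np.concatenate(
                    [rng.poisson(rate_c), rng.poisson(0.9, n_r)]
                ),
                "chosen": [True] * n_c + [False] * n_r,
                "model_r_max": np.concatenate([r_max, np.full(n_r, np.nan)]),
                "proximal": pd.array([True] * (n_c + n_r), dtype="boolean"),
                "role": ["enhancer"] * (n_c + n_r),
            }
        )
        rep = stratified_reports(df, models=None, thresholds=(0.7,))
        assert rep["r_gt_0.7"].enrichment_factor > rep["all"].enrichment_factor

    def test_pipeline_stratified_reports(self, small_pipeline):
        rep = stratified_reports(
            small_pipeline["stats"], small_pipeline["models"], thresholds=(0.7, 0.8)
        )
        assert rep["all"] is not None
        assert rep["all"].enrichment_factor > 1.0
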