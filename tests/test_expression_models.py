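"""Penalized expression models: design, path, selection, LOOCV, partition."""

import numpy as np
import pytest

import crrlink as cl
from crrlink.crr_builder import CRR
from crrlink.expression_models import (
    ENHANCER,
    REPRESSOR,
    ExpressionModel,
    LassoPathPoint,
    ModelConfig,
    candidates_for,
    classify_role,
    design_matrix,
    filter_transcripts,
    fit_lasso_path,
    loocv_r,
    partition_crrs,
    select_lambda,
)
from crrlink.genomic_core import GenomicInterval, TranscriptRecord


def make_transcript(fpkm, tss=0, chrom="chr1"):
    return TranscriptRecord("T1", "G1", chrom, "+", tss, np.asarray(fpkm, float))


def make_crr(start, end, signal=None, chrom="chr1"):
    return CRR(
        crr_id=f"{chrom}:{start}-{end}",
        interval=GenomicInterval(chrom, start, end),
        signal=signal,
    )


def soft_threshold(rho, lam):
    return np.sign(rho) * max(abs(rho) - lam, 0.0)


class TestFilterTranscripts:
    @pytest.mark.parametrize("n_expressed,kept", [(7, True), (6, False), (0, False)])
    def test_expression_breadth_threshold(self, n_expressed, kept):
        fpkm = [1.0] * n_expressed + [0.0] * (14 - n_expressed)
        out = filter_transcripts([make_transcript(fpkm)], ModelConfig())
        assert bool(out) is kept


class TestCandidatesFor:
    config = ModelConfig()

    def test_window_boundary_inclusive(self):
        t = make_transcript([1.0] * 14, tss=0)
        at_edge = make_crr(100_000, 100_100)
        beyond = make_crr(100_001, 100_101)
        out = candidates_for(t, [at_edge, beyond], self.config)
        assert [c.crr_id for c in out] == [at_edge.crr_id]

    def test_other_chromosome_excluded(self):
        t = make_transcript([1.0] * 14, tss=0)
        assert candidates_for(t, [make_crr(0, 100, chrom="chr2")], self.config) == []

    def test_matches_brute_force_scan_on_synthetic_landscape(self, small_pipeline):
        land = small_pipeline["landscape"]
        crrs = small_pipeline["crrs"]
        for t in land.transcripts[:10]:
            got = [c.crr_id for c in candidates_for(t, crrs, self.config)]
            assert tuple(got) == land.truth.candidate_ids[t.transcript_id]


class TestDesignMatrix:
    def test_log_pseudocount_and_roundtrip(self):
        t = make_transcript([0.0, np.e - 1] + [1.0] * 12)
        c = make_crr(0, 10, signal=np.full(14, np.e - 1))
        X, y = design_matrix(t, [c], ModelConfig())
        assert y[0] == pytest.approx(0.0)
        assert y[1] == pytest.approx(1.0)
        assert np.allclose(X[:, 0], 1.0)
        assert np.allclose(np.expm1(y), t.expression)


class TestLassoPath:
    def test_constant_response_gives_empty_path(self):
        X = np.random.default_rng(1).standard_normal((14, 5))
        path = fit_lasso_path(X, np.ones(14))
        assert all(p.n_nonzero == 0 for p in path)
        assert select_lambda(path, 2) is None

    def test_single_predictor_matches_soft_threshold_closed_form(self, rng):
        x = rng.standard_normal(14)
        y = 2.0 * x + rng.normal(0, 0.3, 14)
        X = x.reshape(-1, 1)
        path = fit_lasso_path(X, y)
        sd = x.std()
        xs = (x - x.mean()) / sd
        yc = y - y.mean()
        rho = xs @ yc / len(y)
        for p in path:
            expected_std = soft_threshold(rho, p.lam)
            assert p.coefficients[0] * sd == pytest.approx(expected_std, abs=1e-6)

    def test_path_endpoint_approaches_ols(self, rng):
        X = rng.standard_normal((14, 5))
        beta = np.array([1.5, -2.0, 0.5, 0.0, 1.0])
        y = X @ beta + rng.normal(0, 0.1, 14)
        path = fit_lasso_path(X, y)
        end = min(path, key=lambda p: p.lam)
        ols, *_ = np.linalg.lstsq(np.column_stack([np.ones(14), X]), y, rcond=None)
        assert np.allclose(end.coefficients, ols[1:], atol=0.05)
        assert end.intercept == pytest.approx(ols[0], abs=0.05)

    def test_zero_variance_column_never_selected(self, rng):
        X = rng.standard_normal((14, 3))
        X[:, 1] = 7.0
        y = X[:, 0] + rng.normal(0, 0.1, 14)
        path = fit_lasso_path(X, y)
        assert all(p.coefficients[1] == 0 for p in path)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_lasso_path(np.ones((1, 2)), np.ones(1))


def path_from_counts(counts):
    """Synthetic decreasing-lambda path with the given non-zero counts."""
    points = []
    lam = 1.0
    for c in counts:
        coefs = np.zeros(6)
        coefs[:c] = 1.0
        points.append(LassoPathPoint(lam, coefs, 0.0, c))
        lam /= 2
    return points


class TestSelectLambda:
    def test_exact_target_taken_at_least_shrunk_point(self):
        path = path_from_counts([0, 1, 2, 2, 3])
        chosen = select_lambda(path, 2)
        # the smallest lambda among points with exactly 2 predictors
        assert chosen.n_nonzero == 2
        assert chosen.lam == min(p.lam for p in path if p.n_nonzero == 2)

    def test_fallback_to_largest_count_below_target(self):
        path = path_from_counts([0, 1, 3, 5])
        chosen = select_lambda(path, 2)
        assert chosen.n_nonzero == 1

    def test_all_zero_path_is_failure(self):
        assert select_lambda(path_from_counts([0, 0, 0]), 2) is None

    def test_deterministic_given_path(self):
        path = path_from_counts([0, 1, 2, 3])
        a = select_lambda(path, 2)
        b = select_lambda(path, 2)
        assert a.lam == b.lam and a.n_nonzero == b.n_nonzero


class TestLoocv:
    def test_noiseless_linear_relation_gives_r_near_one(self, rng):
        x = rng.standard_normal(14)
        y = 1.0 + 2.0 * x
        X = np.column_stack([x, rng.standard_normal(14)])
        assert loocv_r(X, y, 1e-8) == pytest.approx(1.0, abs=1e-6)

    def test_three_point_fold_matches_hand_computed_soft_threshold(self):
        # one predictor, three cells; each fold is a closed-form 1D LASSO on
        # two standardized points
        x = np.array([0.0, 1.0, 3.0])
        y = np.array([1.0, 2.0, 2.5])
        lam = 0.1
        preds = []
        for c in range(3):
            mask = np.arange(3) != c
            xt, yt = x[mask], y[mask]
            mu, sd = xt.mean(), xt.std()
            xs = (xt - mu) / sd
            rho = xs @ (yt - yt.mean()) / 2
            w = soft_threshold(rho, lam)
            preds.append(yt.mean() + w * (x[c] - mu) / sd)
        expected = np.corrcoef(preds, y)[0, 1]
        assert loocv_r(x.reshape(-1, 1), y, lam) == pytest.approx(expected, abs=1e-8)

    def test_null_response_scores_far_below_planted(self, small_pipeline, rng):
        models = [m for m in small_pipeline["models"] if m.status == "built"]
        planted_mean = np.mean([m.loocv_r for m in models])
        null_rs = []
        for m in models[:15]:
            X, y = small_pipeline["data"][m.transcript_id]
            null_rs.append(loocv_r(X, rng.permutation(y), m.lambda_star))
        assert planted_mean > 0.8
        assert np.nanmean(null_rs) < 0.1

    def test_planted_beats_permuted_in_paired_comparison(self, small_pipeline):
        from crrlink.significance import permuted_model_r

        models = [m for m in small_pipeline["models"] if m.status == "built"][:20]
        wins = total = 0
        for i, m in enumerate(models):
            X, y = small_pipeline["data"][m.transcript_id]
            null = permuted_model_r(X, y, m.lambda_star, n_perm=3, seed=100 + i)
            for r in null[~np.isnan(null)]:
                total += 1
                wins += m.loocv_r > r
        assert wins / total >= 0.95


class TestPartitionAndRoles:
    def test_partition_rules(self):
        m_a = ExpressionModel("A", ("c1", "c2", "c3"), chosen_crr_ids=("c1",),
                              coefficients={"c1": 0.5}, loocv_r=0.9, status="built")
        m_b = ExpressionModel("B", ("c1", "c2"), status="failed")
        chosen, rejected = partition_crrs([m_a, m_b])
        assert chosen == {"c1"}          # chosen for A despite rejected for B
        assert rejected == {"c2", "c3"}  # candidates never chosen
        assert "c4" not in chosen | rejected

    def test_partition_disjoint_on_pipeline(self, small_pipeline):
        chosen, rejected = partition_crrs(small_pipeline["models"])
        assert chosen and rejected
        assert not chosen & rejected

    def test_role_from_coefficient_sign(self):
        assert classify_role(0.8) == ENHANCER
        assert classify_role(-0.2) == REPRESSOR
        with pytest.raises(ValueError):
            classify_role(0.0)

    def test_planted_repressors_recovered_with_negative_sign(self, small_pipeline):
        land = small_pipeline["landscape"]
        ok = total = 0
        for m in small_pipeline["models"]:
            if m.status != "built":
                continue
            truth = land.truth.coefficients[m.transcript_id]
            for cid, k_true in truth.items():
                if k_true < 0 and cid in m.coefficients:
                    total += 1
                    ok += m.coefficients[cid] < 0
        assert total >= 10
        assert ok / total >= 0.9


class TestModelFitting:
    def test_pipeline_models_select_planted_pair(self, small_pipeline):
        land = small_pipeline["landscape"]
        models = small_pipeline["models"]
        built = [m for m in models if m.status == "built"]
        assert all(1 <= len(m.chosen_crr_ids) <= 2 for m in built)
        hits = sum(
            set(m.chosen_crr_ids) == set(land.truth.regulator_ids[m.transcript_id])
            for m in built
        )
        assert hits / len(models) >= 0.75
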