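"""Mutation-burden comparisons between chosen and rejected CRRs.

Three complementary analyses:

* **Direct tests** — a 2x2 proportion comparison (chi-squared and one-sided
  Fisher) of "mutated at least once", plus Welch t and Wilcoxon rank-sum
  tests on mean mutations per CRR, one-sided in the direction chosen >
  rejected.
* **Confounder-matched resampling** — the rejected set is resampled to match
  the chosen set's distribution of a confounder (replication timing, GC,
  length or TSS distance) using 4 equal-count bins, and the mean-count tests
  are repeated on the size-matched sets.
* **Count GLM** — mutation counts regressed on log length, replication
  timing, GC, log(1 + TSS distance) and a chosen/rejected indicator with a
  log link; when the counts are over-dispersed relative to Poisson the
  standard errors are scaled by the estimated dispersion (quasi-Poisson).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .expression_models import ENHANCER, REPRESSOR, ExpressionModel

logger = logging.getLogger(__name__)

CONFOUNDERS = ("replication_timing", "gc", "length_bp", "nearest_tss_distance")
GLM_COVARIATES = ("log_length", "replication_timing", "gc", "log1p_tss_distance", "chosen")


@dataclass
class EnrichmentResult:
    """All test statistics for one chosen-vs-rejected comparison."""

    label: str
    n_chosen: int
    n_rejected: int
    proportion_mutated_chosen: float
    proportion_mutated_rejected: float
    mean_count_chosen: float
    mean_count_rejected: float
    enrichment_factor: float
    chi2_stat: float = math.nan
    chi2_p: float = math.nan
    fisher_odds: float = math.nan
    fisher_p: float = math.nan
    t_stat: float = math.nan
    t_p: float = math.nan
    wilcoxon_stat: float = math.nan
    wilcoxon_p: float = math.nan


@dataclass
class MatchedResampleResult:
    confounder: str
    n_draws: int
    draws: list[EnrichmentResult]
    mean_enrichment_factor: float
    median_t_p: float
    median_wilcoxon_p: float


@dataclass
class GLMFit:
    """Log-link count regression of mutation counts on CRR covariates."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    dispersion: float
    quasi: bool
    n_used: int


# ---------------------------------------------------------------------------
# Direct comparisons
# ---------------------------------------------------------------------------


def proportion_tests(
    mutated_chosen: int, n_chosen: int, mutated_rejected: int, n_rejected: int
) -> tuple[float, float, float, float]:
    """Chi-squared (two-sided, Yates-corrected) and Fisher (one-sided greater)
    tests on the 2x2 table of mutated-at-least-once by group.

    Returns (chi2 statistic, chi2 p, odds ratio, Fisher p)."""
    table = np.array(
        [
            [mutated_chosen, n_chosen - mutated_chosen],
            [mutated_rejected, n_rejected - mutated_rejected],
        ]
    )
    try:
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(table, correction=True)
    except ValueError:  # a margin of the table is all zero
        chi2_stat, chi2_p = math.nan, math.nan
    odds, fisher_p = stats.fisher_exact(table, alternative="greater")
    return float(chi2_stat), float(chi2_p), float(odds), float(fisher_p)


def compare_groups(
    counts_chosen: Sequence[int],
    counts_rejected: Sequence[int],
    label: str = "chosen_vs_rejected",
) -> EnrichmentResult:
    """All chosen-vs-rejected burden tests on raw per-CRR mutation counts.

    Mean tests are one-sided in the direction chosen > rejected (Welch t and
    Mann-Whitney/Wilcoxon rank-sum); a group with zero count variance leaves
    the t-test p missing while the other tests still run.
    """
    c = np.asarray(counts_chosen, dtype=float)
    r = np.asarray(counts_rejected, dtype=float)
    if c.size == 0 or r.size == 0:
        raise ValueError("both groups must be nonempty")
    mut_c, mut_r = int(np.sum(c > 0)), int(np.sum(r > 0))
    mean_c, mean_r = float(c.mean()), float(r.mean())
    res = EnrichmentResult(
        label=label,
        n_chosen=c.size,
        n_rejected=r.size,
        proportion_mutated_chosen=mut_c / c.size,
        proportion_mutated_rejected=mut_r / r.size,
        mean_count_chosen=mean_c,
        mean_count_rejected=mean_r,
        enrichment_factor=mean_c / mean_r if mean_r > 0 else math.inf,
    )
    res.chi2_stat, res.chi2_p, res.fisher_odds, res.fisher_p = proportion_tests(
        mut_c, c.size, mut_r, r.size
    )
    if c.std(ddof=1) > 0 or r.std(ddof=1) > 0:
        t_stat, t_p = stats.ttest_ind(c, r, equal_var=False, alternative="greater")
        res.t_stat, res.t_p = float(t_stat), float(t_p)
    w_stat, w_p = stats.mannwhitneyu(c, r, alternative="greater")
    res.wilcoxon_stat, res.wilcoxon_p = float(w_stat), float(w_p)
    return res


# ---------------------------------------------------------------------------
# Confounder-matched resampling
# ---------------------------------------------------------------------------


def _bin_edges(values: np.ndarray, n_bins: int, equal_width: bool) -> np.ndarray:
    if equal_width:
        edges = np.linspace(values.min(), values.max(), n_bins + 1)
    else:
        edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    return edges


def matched_resample_test(
    stats_df: pd.DataFrame,
    confounder: str,
    n_bins: int = 4,
    n_draws: int = 100,
    seed: int = 0,
    equal_width: bool = False,
) -> MatchedResampleResult:
    """Repeat the mean-count tests on confounder-matched subsamples.

    Bins are equal-count quartile bins of the *chosen* set's confounder
    values (equal-width available via flag).  Each draw samples, for every
    chosen CRR, one rejected CRR without replacement from the same bin and
    reruns :func:`compare_groups` on the size-matched sets; by construction
    the sampled rejected set reproduces the chosen set's binned confounder
    histogram exactly.  Raises when some bin holds more chosen than rejected
    CRRs.
    """
    rng = np.random.default_rng(seed)
    chosen = stats_df[stats_df["chosen"]]
    rejected = stats_df[~stats_df["chosen"]]
    if chosen.empty or rejected.empty:
        raise ValueError("need both chosen and rejected CRRs")
    cvals = chosen[confounder].to_numpy(dtype=float)
    rvals = rejected[confounder].to_numpy(dtype=float)
    if np.isnan(cvals).any() or np.isnan(rvals).any():
        raise ValueError(f"missing values in confounder {confounder!r}")
    edges = _bin_edges(cvals, n_bins, equal_width)
    cbin = np.digitize(cvals, edges[1:-1])
    rbin = np.digitize(rvals, edges[1:-1])
    ccounts = chosen["mutation_count"].to_numpy()
    rcounts = rejected["mutation_count"].to_numpy()
    need = np.bincount(cbin, minlength=n_bins)
    have = np.bincount(rbin, minlength=n_bins)
    for b in range(n_bins):
        if need[b] > have[b]:
            raise ValueError(
                f"bin {b} of {confounder!r} has {need[b]} chosen but only "
                f"{have[b]} rejected CRRs; cannot match"
            )
    rejected_by_bin = [np.flatnonzero(rbin == b) for b in range(n_bins)]
    draws = []
    for _ in range(n_draws):
        sampled = []
        for b in range(n_bins):
            if need[b] == 0:
                continue
            sampled.append(rng.choice(rejected_by_bin[b], size=need[b], replace=False))
        idx = np.concatenate(sampled)
        draws.append(
            compare_groups(ccounts, rcounts[idx], label=f"matched_{confounder}")
        )
    return MatchedResampleResult(
        confounder=confounder,
        n_draws=n_draws,
        draws=draws,
        mean_enrichment_factor=float(
            np.mean([d.enrichment_factor for d in draws])
        ),
        median_t_p=float(np.nanmedian([d.t_p for d in draws])),
        median_wilcoxon_p=float(np.nanmedian([d.wilcoxon_p for d in draws])),
    )


# ---------------------------------------------------------------------------
# Count GLM
# ---------------------------------------------------------------------------


def fit_mutation_glm(
    stats_df: pd.DataFrame, dispersion_threshold: float = 1.5
) -> GLMFit:
    """Log-link count regression with a quasi-Poisson fallback.

    Counts are modelled on log(length), replication timing, GC,
    log(1 + TSS distance) and the chosen indicator.  The first fit assumes
    unit dispersion (Poisson); if the Pearson chi-squared per degree of
    freedom exceeds ``dispersion_threshold`` the standard errors are rescaled
    by the square root of the estimated dispersion (quasi-likelihood), as the
    counts are then over-dispersed.  Rows with missing covariates are dropped
    with a logged count.
    """
    needed = ["mutation_count", "length_bp", "replication_timing", "gc", "nearest_tss_distance", "chosen"]
    df = stats_df[needed].copy()
    n_before = len(df)
    df = df.dropna()
    if n_before - len(df):
        logger.info("dropped %d CRRs with missing covariates", n_before - len(df))
    if len(df) < 20:
        raise ValueError(f"need >= 20 complete CRRs for the GLM, have {len(df)}")
    y = df["mutation_count"].to_numpy(dtype=float)
    if np.all(y == 0):
        raise ValueError("all mutation counts are zero; GLM is degenerate")
    X = pd.DataFrame(
        {
            "log_length": np.log(df["length_bp"].to_numpy(dtype=float)),
            "replication_timing": df["replication_timing"].to_numpy(dtype=float),
            "gc": df["gc"].to_numpy(dtype=float),
            "log1p_tss_distance": np.log1p(
                df["nearest_tss_distance"].to_numpy(dtype=float)
            ),
            "chosen": df["chosen"].to_numpy(dtype=float),
        }
    )
    X = sm.add_constant(X)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        res = model.fit()
    except Exception as exc:  # perfect separation, non-convergence
        raise RuntimeError(f"count GLM failed to converge: {exc}") from exc
    if not res.converged:
        raise RuntimeError("count GLM did not converge")
    dispersion = float(res.pearson_chi2 / res.df_resid)
    quasi = dispersion > dispersion_threshold
    if quasi:
        logger.info(
            "over-dispersion detected (Pearson chi2/df = %.2f); using quasi-Poisson SEs",
            dispersion,
        )
        res = model.fit(scale="X2")
    bse = res.bse
    z = res.params / bse
    p = 2 * stats.norm.sf(np.abs(z))
    return GLMFit(
        params=res.params,
        bse=bse,
        zvalues=pd.Series(z, index=res.params.index),
        pvalues=pd.Series(p, index=res.params.index),
        dispersion=dispersion,
        quasi=quasi,
        n_used=len(df),
    )


# ---------------------------------------------------------------------------
# Stratified reports
# ---------------------------------------------------------------------------


def stratified_reports(
    stats_df: pd.DataFrame,
    models: Sequence[ExpressionModel] | None = None,
    thresholds: Sequence[float] = (0.7, 0.8),
) -> dict[str, EnrichmentResult | None]:
    """Burden comparisons restricted to higher-quality models and CRR classes.

    For each r threshold the chosen set is restricted to CRRs whose best
    model exceeds it; the rejected set is restricted to candidates of those
    same qualifying models (the comparison stays within the transcripts that
    produced the stratum).  Also reports proximal-vs-distal and
    enhancer-vs-repressor comparisons within the chosen set.  Empty strata
    map to None.
    """
    out: dict[str, EnrichmentResult | None] = {}
    chosen = stats_df[stats_df["chosen"]]
    rejected = stats_df[~stats_df["chosen"]]
    out["all"] = (
        compare_groups(chosen["mutation_count"], rejected["mutation_count"], "all")
        if len(chosen) and len(rejected)
        else None
    )
    for thr in thresholds:
        label = f"r_gt_{thr:g}"
        c_sub = chosen[chosen["model_r_max"] > thr]
        if models is not None:
            qualifying = {
                cid
                for m in models
                if m.status == "built" and m.loocv_r > thr
                for cid in m.candidate_crr_ids
            }
            r_sub = rejected[rejected["crr_id"].isin(qualifying)]
        else:
            r_sub = rejected
        out[label] = (
            compare_groups(c_sub["mutation_count"], r_sub["mutation_count"], label)
            if len(c_sub) and len(r_sub)
            else None
        )
    prox = chosen[chosen["proximal"] == True]  # noqa: E712 (boolean dtype with NA)
    dist = chosen[chosen["proximal"] == False]  # noqa: E712
    out["proximal_vs_distal"] = (
        compare_groups(
            prox["mutation_count"], dist["mutation_count"], "proximal_vs_distal"
        )
        if len(prox) and len(dist)
        else None
    )
    enh = chosen[chosen["role"] == ENHANCER]
    rep = chosen[chosen["role"] == REPRESSOR]
    out["enhancer_vs_repressor"] = (
        compare_groups(
            enh["mutation_count"], rep["mutation_count"], "enhancer_vs_repressor"
        )
        if len(enh) and len(rep)
        else None
    )
    return out
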