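"""Permutation-based empirical significance for expression models.

Model quality under the null is assessed by fixing the DNase design matrix
and permuting the expression vector across cell types: each permutation is
refitted at the lambda chosen for the real model and its leave-one-out
correlation recorded.  Because the null distribution of these correlations is
very similar across transcripts, permutations from a small stratified sample
of transcripts (high-r, moderate-r and failed models) are pooled into one
null distribution used to compute empirical p-values for every model, which
are then adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .expression_models import (
    ExpressionModel,
    ModelConfig,
    fit_lasso_path,
    loocv_r,
    select_lambda,
)

logger = logging.getLogger(__name__)


@dataclass
class PermutationNull:
    """A pooled null distribution of leave-one-out correlations."""

    null_correlations: np.ndarray
    n_perm: int
    source_transcripts: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        vals = self.null_correlations[~np.isnan(self.null_correlations)]
        if vals.size and (np.any(vals < -1) or np.any(vals > 1)):
            raise ValueError("null correlations must lie in [-1, 1]")


def permuted_model_r(
    X: np.ndarray,
    y: np.ndarray,
    lambda_star: float | None,
    n_perm: int,
    seed: int | np.random.Generator,
    config: ModelConfig | None = None,
) -> np.ndarray:
    """Null leave-one-out correlations from permuted expression vectors.

    Each permutation shuffles the entries of ``y`` and refits at the fixed
    penalty ``lambda_star``.  When ``lambda_star`` is None (the real model
    failed, so there is no lambda to fix) each permutation reruns the full
    path-and-selection procedure.  Failed permuted fits are recorded as nan;
    callers exclude them from the null.  A constant ``y`` makes every
    permutation identical and the null degenerate; this is flagged with a
    warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    y = np.asarray(y, dtype=float)
    if np.allclose(y, y[0]):
        logger.warning("constant expression vector: permutation null is degenerate")
    config = config or ModelConfig()
    out = np.full(n_perm, np.nan)
    for i in range(n_perm):
        yp = rng.permutation(y)
        if lambda_star is None:
            path = fit_lasso_path(X, yp, config.n_alphas, config.path_eps)
            point = select_lambda(path, config.target_nonzero)
            if point is None:
                continue
            lam = point.lam
        else:
            lam = lambda_star
        out[i] = loocv_r(X, yp, lam)
    return out


def stratify_models(
    models: Sequence[ExpressionModel],
    high_r: float = 0.8,
    moderate_band: tuple[float, float] = (0.3, 0.7),
) -> dict[str, list[ExpressionModel]]:
    """Assign models to the high / moderate / failed strata used for pooling."""
    strata: dict[str, list[ExpressionModel]] = {"high": [], "moderate": [], "failed": []}
    for m in models:
        if m.status != "built":
            strata["failed"].append(m)
        elif m.loocv_r >= high_r:
            strata["high"].append(m)
        elif moderate_band[0] <= m.loocv_r <= moderate_band[1]:
            strata["moderate"].append(m)
    return strata


def build_pooled_null(
    models: Sequence[ExpressionModel],
    data_by_transcript: dict[str, tuple[np.ndarray, np.ndarray]],
    n_perm: int = 1000,
    n_per_stratum: int = 4,
    seed: int = 0,
    config: ModelConfig | None = None,
    high_r: float = 0.8,
    moderate_band: tuple[float, float] = (0.3, 0.7),
) -> PermutationNull:
    """Pool permutation correlations from a stratified sample of transcripts.

    ``data_by_transcript`` maps transcript id to its (X, y) design; the
    sample takes up to ``n_per_stratum`` transcripts from each of the high-r,
    moderate-r and failed strata (a stratum with no transcripts is skipped
    with a warning).  All permutation randomness derives from ``seed``.
    """
    rng = np.random.default_rng(seed)
    strata = stratify_models(models, high_r, moderate_band)
    sources: list[ExpressionModel] = []
    for name in ("high", "moderate", "failed"):
        pool = [m for m in strata[name] if m.transcript_id in data_by_transcript]
        if not pool:
            logger.warning("no transcripts available in stratum %r; skipping", name)
            continue
        take = min(n_per_stratum, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        sources.extend(pool[i] for i in idx)
    if not sources:
        raise ValueError("no transcripts available for the pooled null")
    null_vals = []
    for m in sources:
        X, y = data_by_transcript[m.transcript_id]
        r = permuted_model_r(
            X, y, m.lambda_star if m.status == "built" else None, n_perm, rng, config
        )
        null_vals.append(r[~np.isnan(r)])
    pooled = np.concatenate(null_vals) if null_vals else np.array([])
    return PermutationNull(
        null_correlations=pooled,
        n_perm=n_perm,
        source_transcripts=tuple(m.transcript_id for m in sources),
        seed=seed,
    )


def empirical_p(r_obs: float, null: PermutationNull | np.ndarray) -> float:
    """Add-one empirical p-value: ``(1 + #{r_null >= r_obs}) / (1 + N)``.

    The add-one rule bounds p below by 1/(N+1), so a real correlation larger
    than every null value gets p = 1/(N+1), never 0.
    """
    vals = null.null_correlations if isinstance(null, PermutationNull) else np.asarray(null)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(vals >= r_obs)) / (1 + vals.size))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_significance(
    models: Sequence[ExpressionModel],
    data_by_transcript: dict[str, tuple[np.ndarray, np.ndarray]],
    n_perm: int = 1000,
    n_per_stratum: int = 4,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> PermutationNull:
    """Compute pooled-null p-values and BH q-values for all built models, in place."""
    null = build_pooled_null(
        models, data_by_transcript, n_perm, n_per_stratum, seed, config
    )
    built = [m for m in models if m.status == "built"]
    for m in built:
        m.p_value = empirical_p(m.loocv_r, null)
    qs = bh_adjust([m.p_value for m in built])
    for m, q in zip(built, qs):
        m.q_value = float(q)
    return null
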