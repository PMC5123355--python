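"""Penalized per-transcript models of expression on CRR DNase signal.

For each transcript the model is a linear relationship between log expression
and log DNase signal intensity in the candidate CRRs within 100 kb of its TSS:

    y = k0 + sum_i k_i * x_i

with y = log(FPKM + 1) per cell type and x_i = log(signal_i + 1).  Because the
number of candidates (typically ~42) exceeds the number of cell types (14),
the fit is L1-penalized (LASSO); the penalty scale lambda is chosen
conservatively as the largest value on the regularization path that yields
exactly ``target_nonzero`` (default 2) non-zero coefficients.  Model quality
is the Pearson correlation r between observed expression and predictions from
leave-one-cell-type-out refits at the chosen lambda.

CRRs that receive a non-zero coefficient in at least one built model are the
"chosen" set; CRRs that were candidates for some model but never received a
non-zero coefficient are the "rejected" set.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

from .crr_builder import CRR
from .genomic_core import TranscriptRecord, tss_distance

logger = logging.getLogger(__name__)

ENHANCER = "enhancer"
REPRESSOR = "repressor"


@dataclass
class ModelConfig:
    window_bp: int = 100_000
    fpkm_min: float = 1.0
    min_expressed_cells: int = 7
    target_nonzero: int = 2
    log_pseudocount: float = 1.0
    n_alphas: int = 100
    path_eps: float = 1e-3

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.target_nonzero < 1:
            raise ValueError("target_nonzero must be >= 1")
        if self.min_expressed_cells < 1:
            raise ValueError("min_expressed_cells must be >= 1")


@dataclass
class LassoPathPoint:
    lam: float
    coefficients: np.ndarray  # original (unstandardized) scale
    intercept: float
    n_nonzero: int


@dataclass
class ExpressionModel:
    """The fitted model for one transcript; ``status`` is 'built' or 'failed'."""

    transcript_id: str
    candidate_crr_ids: tuple[str, ...]
    chosen_crr_ids: tuple[str, ...] = ()
    lambda_star: float | None = None
    intercept: float = float("nan")
    coefficients: dict[str, float] = field(default_factory=dict)
    loocv_r: float = float("nan")
    p_value: float | None = None
    q_value: float | None = None
    status: str = "failed"


# ---------------------------------------------------------------------------
# Candidate assembly
# ---------------------------------------------------------------------------


def filter_transcripts(
    transcripts: Sequence[TranscriptRecord], config: ModelConfig
) -> list[TranscriptRecord]:
    """Keep transcripts expressed (FPKM >= fpkm_min) in >= min_expressed_cells cells."""
    kept = []
    for t in transcripts:
        if t.expression is None:
            continue
        if int(np.sum(t.expression >= config.fpkm_min)) >= config.min_expressed_cells:
            kept.append(t)
    return kept


def candidates_for(
    transcript: TranscriptRecord, crrs: Sequence[CRR], config: ModelConfig
) -> list[CRR]:
    """CRRs on the transcript's chromosome within window_bp of its TSS, in genomic order."""
    cands = [
        c
        for c in crrs
        if c.interval.chrom == transcript.chrom
        and tss_distance(c.interval, transcript.tss) <= config.window_bp
    ]
    cands.sort(key=lambda c: c.interval.start)
    return cands


def design_matrix(
    transcript: TranscriptRecord, candidates: Sequence[CRR], config: ModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Log-transformed design matrix (cells x candidates) and response vector."""
    if not candidates:
        raise ValueError("no candidate CRRs")
    if transcript.expression is None:
        raise ValueError(f"transcript {transcript.transcript_id} has no expression")
    y = np.log(transcript.expression + config.log_pseudocount)
    X = np.column_stack(
        [np.log(c.signal + config.log_pseudocount) for c in candidates]
    )
    return X, y


# ---------------------------------------------------------------------------
# Penalized fitting
# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def fit_lasso_path(
    X: np.ndarray, y: np.ndarray, n_alphas: int = 100, eps: float = 1e-3
) -> list[LassoPathPoint]:
    """Compute a decreasing-lambda LASSO path.

    Predictors are standardized (mean 0, unit variance) for the fit and
    coefficients are mapped back to the original scale.  Zero-variance
    columns always carry coefficient 0.  The path starts at lambda_max (all
    coefficients exactly 0) and ends near 0.

    Lambda here is the coordinate-descent penalty on the standardized scale,
    i.e. the objective is ``(1/2n)||y - Xw||^2 + lambda * ||w||_1``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations to fit")
    Xs, mu, sd = _standardize(X)
    yc = y - y.mean()
    if np.allclose(yc, 0):
        # constant response: the penalized problem is degenerate, every
        # coefficient is 0 at any lambda
        coefs = np.zeros(X.shape[1])
        return [LassoPathPoint(0.0, coefs, float(y.mean()), 0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # tight tolerance: the default duality-gap stopping rule leaves
        # visible coefficient error along the warm-started path
        try:
            alphas, coefs, _ = lasso_path(Xs, yc, eps=eps, alphas=n_alphas, tol=1e-8)
        except (TypeError, ValueError):  # older scikit-learn: alphas must be an array
            alphas, coefs, _ = lasso_path(Xs, yc, eps=eps, n_alphas=n_alphas, tol=1e-8)
    points = []
    for j, lam in enumerate(alphas):
        k_std = coefs[:, j]
        k = k_std / sd
        k[X.std(axis=0) == 0] = 0.0
        intercept = float(y.mean() - k @ mu)
        points.append(
            LassoPathPoint(float(lam), k, intercept, int(np.sum(k_std != 0)))
        )
    return points


def select_lambda(
    path: Sequence[LassoPathPoint], target_nonzero: int
) -> LassoPathPoint | None:
    """Choose the penalty so that exactly ``target_nonzero`` coefficients survive.

    Among path points with exactly the target count, the *smallest* lambda is
    taken — the least-shrunk (best-fitting) model with that many predictors,
    i.e. the end of the target-count stretch of the path just before an
    additional predictor enters.  (At the other end of the stretch, where the
    last predictor has only just entered, its coefficient is still shrunk to
    nearly zero and the model has essentially no predictive value.)

    If no path point hits the target, fall back to the largest count below
    the target seen on the path, again at its smallest lambda (conservative:
    fewer predictors than requested).  Returns None (failure) when no path
    point has between 1 and ``target_nonzero`` non-zero coefficients — in
    particular when the whole path is empty of signal.
    """
    if not path:
        raise ValueError("empty path")
    ordered = sorted(path, key=lambda p: p.lam)  # increasing lambda
    for target in (target_nonzero, *range(target_nonzero - 1, 0, -1)):
        for p in ordered:
            if p.n_nonzero == target:
                return p
    return None


def _lasso_fit(Xs: np.ndarray, y: np.ndarray, lam: float) -> Lasso:
    model = Lasso(alpha=max(lam, 1e-12), max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # inputs are built in-house (finite float64); skipping sklearn's
        # validation matters in the permutation loops
        model.fit(np.asfortranarray(Xs), np.ascontiguousarray(y), check_input=False)
    return model


def loocv_r(X: np.ndarray, y: np.ndarray, lambda_star: float) -> float:
    """Leave-one-cell-type-out correlation at a fixed penalty.

    Each fold refits the LASSO at ``lambda_star`` on the remaining cells
    (standardizing predictors within the training fold) and predicts the
    held-out cell.  Returns the Pearson correlation of held-out predictions
    with the observed response, or ``nan`` when either side is constant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations for LOOCV")
    preds = np.empty(n)
    for c in range(n):
        mask = np.arange(n) != c
        Xtr, ytr = X[mask], y[mask]
        Xs, mu, sd = _standardize(Xtr)
        model = _lasso_fit(Xs, ytr, lambda_star)
        preds[c] = model.predict(((X[c] - mu) / sd).reshape(1, -1))[0]
    if np.std(preds) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(preds, y)[0])


def fit_transcript_model(
    transcript: TranscriptRecord,
    candidates: Sequence[CRR],
    config: ModelConfig,
) -> ExpressionModel:
    """Full single-transcript fit: path, lambda selection, LOOCV quality."""
    cand_ids = tuple(c.crr_id for c in candidates)
    model = ExpressionModel(transcript.transcript_id, cand_ids)
    if not candidates:
        return model
    X, y = design_matrix(transcript, candidates, config)
    path = fit_lasso_path(X, y, config.n_alphas, config.path_eps)
    point = select_lambda(path, config.target_nonzero)
    if point is None:
        return model
    r = loocv_r(X, y, point.lam)
    if np.isnan(r):
        return model
    chosen = tuple(
        cand_ids[i] for i in np.flatnonzero(point.coefficients != 0)
    )
    model.chosen_crr_ids = chosen
    model.lambda_star = point.lam
    model.intercept = point.intercept
    model.coefficients = {
        cand_ids[i]: float(point.coefficients[i])
        for i in np.flatnonzero(point.coefficients != 0)
    }
    model.loocv_r = r
    model.status = "built"
    return model


def fit_all_models(
    transcripts: Sequence[TranscriptRecord],
    crrs: Sequence[CRR],
    config: ModelConfig | None = None,
    gene_subset: set[str] | None = None,
) -> list[ExpressionModel]:
    """Fit models for every transcript passing the expression filter.

    A model is "attempted" when the transcript passes the FPKM filter and has
    at least one candidate CRR in its window; attempted-but-unbuilt models
    keep status 'failed' and still contribute their candidates to the
    rejected set.  ``gene_subset`` optionally restricts to a gene-id list
    (e.g. a cancer gene census).
    """
    config = config or ModelConfig()
    kept = filter_transcripts(transcripts, config)
    if gene_subset is not None:
        kept = [t for t in kept if t.gene_id in gene_subset]
    models = []
    for t in kept:
        cands = candidates_for(t, crrs, config)
        if not cands:
            continue
        models.append(fit_transcript_model(t, cands, config))
    n_built = sum(m.status == "built" for m in models)
    logger.info("attempted %d models, built %d", len(models), n_built)
    return models


# ---------------------------------------------------------------------------
# Chosen / rejected partition
# ---------------------------------------------------------------------------


def partition_crrs(models: Sequence[ExpressionModel]) -> tuple[set[str], set[str]]:
    """Split CRR ids into chosen (non-zero coefficient in >=1 built model) and
    rejected (candidate in >=1 attempted model, never chosen).  CRRs that were
    never in any window belong to neither set."""
    chosen: set[str] = set()
    considered: set[str] = set()
    for m in models:
        considered.update(m.candidate_crr_ids)
        if m.status == "built":
            chosen.update(m.chosen_crr_ids)
    return chosen, considered - chosen


def classify_role(coefficient: float) -> str:
    """Label a chosen CRR by the sign of its effect on expression."""
    if coefficient > 0:
        return ENHANCER
    if coefficient < 0:
        return REPRESSOR
    raise ValueError("zero coefficient has no role; only chosen CRRs are classified")
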