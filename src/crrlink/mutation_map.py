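"""Map a somatic-mutation catalogue onto CRRs and build per-CRR statistics.

Recurrent mutations are collapsed so that each genomic location contributes
at most one mutation, then counts are accumulated per CRR.  Each CRR row also
carries the covariates used by the enrichment tests (length, GC, replication
timing, TSS distance), its chosen/rejected status, its enhancer/repressor
role, and the best leave-one-out r among the models that chose it.

The per-CRR table is a pandas DataFrame with columns::

    crr_id, mutation_count, chosen, length_bp, gc, replication_timing,
    nearest_tss_distance, proximal, role, model_r_max
"""

from __future__ import annotations

import logging
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .crr_builder import CRR
from .expression_models import ExpressionModel, classify_role
from .genomic_core import Mutation, TranscriptRecord, overlap_count, tss_distance

logger = logging.getLogger(__name__)

PROXIMAL_THRESHOLD_BP = 10_000

STATS_COLUMNS = [
    "crr_id",
    "mutation_count",
    "chosen",
    "length_bp",
    "gc",
    "replication_timing",
    "nearest_tss_distance",
    "proximal",
    "role",
    "model_r_max",
]


def dedup_mutations(mutations: Sequence[Mutation]) -> list[Mutation]:
    """Collapse to one mutation per (chrom, 1-based pos); first occurrence wins.

    The deduplication key is the location only — not the alleles — so a
    recurrent position with different substitutions still counts once.
    Output is sorted by (chrom, pos).
    """
    seen: dict[tuple[str, int], Mutation] = {}
    for m in mutations:
        seen.setdefault((m.chrom, m.pos), m)
    return [seen[k] for k in sorted(seen)]


def count_mutations_per_crr(
    mutations_dedup: Sequence[Mutation], crrs: Sequence[CRR]
) -> np.ndarray:
    """Count deduplicated mutations per CRR (1-based positions -> 0-based).

    A mutation at 1-based position ``p`` hits CRR ``[start, end)`` iff
    ``start <= p - 1 < end``.  Returns counts aligned with ``crrs``; CRRs with
    no mutations get 0.
    """
    points = [(m.chrom, m.pos - 1) for m in mutations_dedup]
    return overlap_count(points, [c.interval for c in crrs])


def associated_tss_distances(
    crrs: Sequence[CRR],
    models: Sequence[ExpressionModel],
    transcripts: Sequence[TranscriptRecord],
) -> tuple[dict[str, float], dict[str, str], dict[str, float]]:
    """Per-CRR association summaries derived from the fitted models.

    Returns three mappings keyed by crr_id:

    * distance to the nearest *associated* TSS — for a chosen CRR the
      transcripts whose built model chose it, for other considered CRRs the
      transcripts for which it was a candidate;
    * role (enhancer/repressor) from the sign of the coefficient in the
      best-r model choosing the CRR;
    * best leave-one-out r among models choosing the CRR.
    """
    tss_by_id = {t.transcript_id: t for t in transcripts}
    crr_by_id = {c.crr_id: c for c in crrs}
    dist: dict[str, float] = {}
    candidate_dist: dict[str, float] = {}
    role: dict[str, str] = {}
    r_max: dict[str, float] = {}
    best_r_for_role: dict[str, float] = {}
    for m in models:
        t = tss_by_id.get(m.transcript_id)
        if t is None:
            continue
        for cid in m.candidate_crr_ids:
            crr = crr_by_id.get(cid)
            if crr is None:
                continue
            d = tss_distance(crr.interval, t.tss)
            candidate_dist[cid] = min(candidate_dist.get(cid, math.inf), d)
        if m.status != "built":
            continue
        for cid, k in m.coefficients.items():
            crr = crr_by_id.get(cid)
            if crr is None:
                continue
            d = tss_distance(crr.interval, t.tss)
            dist[cid] = min(dist.get(cid, math.inf), d)
            r_max[cid] = max(r_max.get(cid, -math.inf), m.loocv_r)
            if m.loocv_r > best_r_for_role.get(cid, -math.inf):
                best_r_for_role[cid] = m.loocv_r
                role[cid] = classify_role(k)
    # chosen CRRs use the TSS of the transcripts that chose them; others fall
    # back to the nearest candidate-window TSS
    for cid, d in candidate_dist.items():
        dist.setdefault(cid, d)
    return dist, role, r_max


def annotate_proximity(
    stats: pd.DataFrame, threshold: int = PROXIMAL_THRESHOLD_BP
) -> pd.DataFrame:
    """Add the proximal flag: distance < threshold; exactly at threshold is distal.

    CRRs with a missing association distance get a missing (NA) flag and are
    excluded from proximal/distal comparisons downstream.
    """
    out = stats.copy()
    d = out["nearest_tss_distance"]
    out["proximal"] = pd.array(
        np.where(d.notna(), d < threshold, None), dtype="boolean"
    )
    return out


def build_mutation_stats(
    crrs: Sequence[CRR],
    models: Sequence[ExpressionModel],
    transcripts: Sequence[TranscriptRecord],
    mutations: Sequence[Mutation],
    proximal_threshold: int = PROXIMAL_THRESHOLD_BP,
) -> pd.DataFrame:
    """Assemble the per-CRR mutation-statistics table.

    Only CRRs that were candidates for at least one attempted model appear
    (the chosen/rejected universe); mutations are deduplicated here.  The
    run log reports the fraction of mutations mapping to CRRs and the
    fraction of CRRs mutated at least once.
    """
    from .expression_models import partition_crrs

    chosen_ids, rejected_ids = partition_crrs(models)
    universe = chosen_ids | rejected_ids
    kept = [c for c in crrs if c.crr_id in universe]
    dedup = dedup_mutations(mutations)
    counts = count_mutations_per_crr(dedup, kept)
    dist, role, r_max = associated_tss_distances(kept, models, transcripts)
    rows = []
    for crr, n_mut in zip(kept, counts):
        rows.append(
            {
                "crr_id": crr.crr_id,
                "mutation_count": int(n_mut),
                "chosen": crr.crr_id in chosen_ids,
                "length_bp": crr.length_bp,
                "gc": crr.gc,
                "replication_timing": crr.replication_timing,
                "nearest_tss_distance": dist.get(crr.crr_id, np.nan),
                "role": role.get(crr.crr_id, "none"),
                "model_r_max": r_max.get(crr.crr_id, np.nan),
            }
        )
    stats = pd.DataFrame(rows, columns=[c for c in STATS_COLUMNS if c != "proximal"])
    stats = annotate_proximity(stats, proximal_threshold)
    stats = stats[STATS_COLUMNS]
    if dedup:
        frac_mapped = counts.sum() / len(dedup)
        logger.info(
            "%.1f%% of %d deduplicated mutations map to CRRs",
            100 * frac_mapped,
            len(dedup),
        )
    if len(stats):
        logger.info(
            "%.1f%% of %d CRRs carry at least one mutation",
            100 * (stats["mutation_count"] > 0).mean(),
            len(stats),
        )
    return stats
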