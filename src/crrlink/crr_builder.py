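"""Build the candidate regulatory region (CRR) set from per-cell-type peaks.

A CRR is a merged genomic interval formed from transcription-factor binding
sites (all of them) plus the highest-scoring quarter of DNase I hypersensitive
sites, where the DHS component is additionally required to carry the H3K27ac
active-enhancer mark in at least one cell type.  Each CRR then receives a
per-cell-type DNase signal vector (per-base mean of the normalised signal
track over the region) and covariates used downstream: length, GC fraction,
replication timing and distance to the nearest TSS.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np

from .genomic_core import (
    BedGraphTrack,
    GenomicInterval,
    Peak,
    gc_fraction,
    merge_intervals,
)

logger = logging.getLogger(__name__)


@dataclass
class BuildConfig:
    """Configuration of the CRR build.

    ``cell_types`` fixes the order of every per-cell-type signal vector.
    ``dhs_top_fraction`` is the score quantile of DHS peaks retained per cell
    type (0.25 keeps the top quarter).
    """

    cell_types: tuple[str, ...]
    dhs_top_fraction: float = 0.25
    require_h3k27ac: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.dhs_top_fraction <= 1:
            raise ValueError(
                f"dhs_top_fraction must be in (0, 1], got {self.dhs_top_fraction}"
            )


@dataclass
class CRR:
    """A merged candidate regulatory region with signal and covariates."""

    crr_id: str
    interval: GenomicInterval
    signal: np.ndarray | None = None  # mean DNase signal per cell type
    gc: float = math.nan
    replication_timing: float = math.nan
    bound_factors: frozenset[str] = frozenset()
    nearest_tss_distance: int | None = None

    @property
    def length_bp(self) -> int:
        return self.interval.length

    def __post_init__(self) -> None:
        if self.signal is not None:
            self.signal = np.asarray(self.signal, dtype=float)
            if np.any(self.signal < 0):
                raise ValueError(f"negative signal in {self.crr_id}")


def crr_id_for(interval: GenomicInterval) -> str:
    """Stable coordinate-derived identifier, e.g. ``chr1:100-300``."""
    return f"{interval.chrom}:{interval.start}-{interval.end}"


def select_top_dhs(dhs_peaks: Sequence[Peak], fraction: float) -> list[Peak]:
    """Keep the highest-scoring ``fraction`` of DHS peaks within each cell type.

    Retains ``ceil(fraction * n)`` peaks per cell type; ties at the score
    threshold are all retained, so slightly more than the nominal fraction may
    survive.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    by_cell: dict[str, list[Peak]] = defaultdict(list)
    for p in dhs_peaks:
        if p.assay != "DHS":
            raise ValueError(f"select_top_dhs expects DHS peaks, got {p.assay}")
        by_cell[p.cell_type].append(p)
    kept: list[Peak] = []
    for peaks in by_cell.values():
        n_keep = math.ceil(fraction * len(peaks))
        scores = sorted((p.score for p in peaks), reverse=True)
        threshold = scores[n_keep - 1]
        kept.extend(p for p in peaks if p.score >= threshold)
    return kept


def filter_by_h3k27ac(
    dhs_peaks: Sequence[Peak], h3k27ac_peaks: Sequence[Peak]
) -> list[Peak]:
    """Keep DHS peaks overlapping (>=1 bp) any H3K27ac peak from any cell type."""
    marks = merge_intervals([p.interval for p in h3k27ac_peaks]) if h3k27ac_peaks else []
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in marks:
        grouped[iv.chrom].append(iv)
    for chrom, ivs in grouped.items():
        by_chrom[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    kept = []
    for p in dhs_peaks:
        entry = by_chrom.get(p.interval.chrom)
        if entry is None:
            continue
        starts, ends = entry
        # overlap iff some mark has start < p.end and end > p.start
        i = int(np.searchsorted(starts, p.interval.end, side="left")) - 1
        if i >= 0 and ends[i] > p.interval.start:
            kept.append(p)
    return kept


def build_crrs(
    tfbs_peaks: Sequence[Peak],
    dhs_peaks: Sequence[Peak],
    h3k27ac_peaks: Sequence[Peak],
    config: BuildConfig,
) -> list[CRR]:
    """Construct the full CRR set.

    Pipeline: per-cell-type top-fraction DHS selection, H3K27ac filtering of
    the DHS component (TFBS are exempt), then a >=1 bp overlap merge of the
    union.  ``bound_factors`` of each CRR is the union of TF names of the TFBS
    merged into it.
    """
    dhs_kept = select_top_dhs(dhs_peaks, config.dhs_top_fraction) if dhs_peaks else []
    if config.require_h3k27ac:
        dhs_kept = filter_by_h3k27ac(dhs_kept, h3k27ac_peaks)
    retained = list(tfbs_peaks) + dhs_kept
    if not retained:
        logger.warning("no peaks retained; CRR set is empty")
        return []
    merged = merge_intervals([p.interval for p in retained])
    # assign TF names to the merged region containing each TFBS
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in merged:
        by_chrom[iv.chrom].append(iv)
    index = {
        chrom: (np.array([iv.start for iv in ivs]), np.array([iv.end for iv in ivs]))
        for chrom, ivs in by_chrom.items()
    }
    factors: dict[tuple[str, int], set[str]] = defaultdict(set)
    for p in tfbs_peaks:
        if p.factor is None:
            continue
        starts, ends = index[p.interval.chrom]
        i = int(np.searchsorted(starts, p.interval.start, side="right")) - 1
        if i >= 0 and p.interval.start < ends[i]:
            factors[(p.interval.chrom, int(starts[i]))].add(p.factor)
    crrs = [
        CRR(
            crr_id=crr_id_for(iv),
            interval=iv,
            bound_factors=frozenset(factors.get((iv.chrom, iv.start), set())),
        )
        for iv in merged
    ]
    crrs.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return crrs


def attach_signal(
    crrs: Sequence[CRR],
    signal_tracks: Mapping[str, BedGraphTrack],
    config: BuildConfig,
) -> list[CRR]:
    """Attach the per-cell-type DNase signal vector to each CRR.

    The value for cell type ``c`` is the per-base mean of that cell type's
    track over the CRR interval, with uncovered positions contributing 0.
    Vector order follows ``config.cell_types``.
    """
    for ct in config.cell_types:
        if ct not in signal_tracks:
            raise ValueError(f"missing signal track for cell type {ct!r}")
    out = []
    for crr in crrs:
        iv = crr.interval
        vec = np.array(
            [signal_tracks[ct].mean(iv.chrom, iv.start, iv.end) for ct in config.cell_types]
        )
        out.append(replace(crr, signal=vec))
    return out


def attach_covariates(
    crrs: Sequence[CRR],
    sequences: Mapping[str, str] | None = None,
    replication_timing: BedGraphTrack | None = None,
) -> list[CRR]:
    """Attach GC fraction and replication timing covariates where available."""
    out = []
    for crr in crrs:
        iv = crr.interval
        gc = gc_fraction(iv, sequences) if sequences is not None else crr.gc
        rt = (
            replication_timing.mean(iv.chrom, iv.start, iv.end)
            if replication_timing is not None
            else crr.replication_timing
        )
        out.append(replace(crr, gc=gc, replication_timing=rt))
    return out
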