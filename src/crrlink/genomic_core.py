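"""Coordinate conventions, interval algebra, and flat-file readers/writers.

Conventions used throughout the package:

* Intervals are BED-style: 0-based, half-open ``[start, end)``.
* Mutation catalogues carry 1-based positions (COSMIC/VCF convention);
  they are converted to 0-based (``pos - 1``) at the point where they are
  intersected with intervals, never before.
* Chromosome names are matched by exact string comparison; no ``chr``
  prefix normalisation is attempted.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ASSAYS = ("TFBS", "DHS", "H3K27ac")
STRANDS = ("+", "-", ".")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least 1 bp (abutting does not count)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A scored peak call from one assay in one cell type."""

    interval: GenomicInterval
    score: float = 0.0
    cell_type: str = ""
    assay: str = "DHS"
    factor: str | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        if self.factor is not None and self.assay != "TFBS":
            raise ValueError("factor may only be set for TFBS peaks")


@dataclass
class TranscriptRecord:
    """A transcript anchored at its TSS with a per-cell-type expression vector.

    ``tss`` is a 0-based position.  For minus-strand transcripts the TSS is
    the annotated transcript *end* coordinate; annotation tables are expected
    to supply a precomputed TSS column so no strand arithmetic happens here.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int
    expression: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.expression is not None:
            self.expression = np.asarray(self.expression, dtype=float)
            if np.any(self.expression < 0):
                raise ValueError(
                    f"negative FPKM in expression vector of {self.transcript_id}"
                )


@dataclass(frozen=True)
class Mutation:
    """A somatic mutation at a 1-based genomic position."""

    chrom: str
    pos: int  # 1-based
    ref: str | None = None
    alt: str | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"mutation position is 1-based, got {self.pos}")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals that overlap by at least 1 bp.

    Two inputs end up in the same output interval iff they are connected by a
    chain of >=1 bp overlaps.  Abutting intervals (``end == start``) share 0 bp
    and are NOT merged.  Output is sorted by (chrom, start) and pairwise
    disjoint; strand is dropped (merged regions are unstranded).
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:  # strict: abutting does not merge
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def _disjoint_index(
    targets: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Index pairwise-disjoint targets per chromosome; raises if they overlap."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for idx, t in enumerate(targets):
        by_chrom[t.chrom].append((t.start, t.end, idx))
    index = {}
    for chrom, triples in by_chrom.items():
        triples.sort()
        starts = np.array([t[0] for t in triples])
        ends = np.array([t[1] for t in triples])
        idxs = np.array([t[2] for t in triples])
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"targets overlap on {chrom}; merge them first")
        index[chrom] = (starts, ends, idxs)
    return index


def overlap_count(
    points: Sequence[tuple[str, int]], targets: Sequence[GenomicInterval]
) -> np.ndarray:
    """Count points falling in each target interval.

    Points are ``(chrom, 0-based position)`` pairs.  A point ``p`` is counted
    for target ``t`` iff ``t.start <= p < t.end``; because targets must be
    pairwise disjoint each point is counted at most once.  Returns counts in
    the order of ``targets``.
    """
    index = _disjoint_index(targets)
    counts = np.zeros(len(targets), dtype=int)
    for chrom, pos in points:
        entry = index.get(chrom)
        if entry is None:
            continue
        starts, ends, idxs = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            counts[idxs[i]] += 1
    return counts


def tss_distance(crr: GenomicInterval, tss: int) -> int:
    """Distance in bp from a TSS to the nearest edge of an interval.

    0 if the TSS lies inside ``[start, end)``; otherwise the distance to the
    nearest contained base (``start`` or ``end - 1``).
    """
    if crr.start <= tss < crr.end:
        return 0
    return min(abs(tss - crr.start), abs(tss - (crr.end - 1)))


def gc_fraction(
    interval: GenomicInterval, sequences: Mapping[str, str]
) -> float:
    """GC fraction of an interval, case-insensitive, ignoring ambiguous bases.

    Returns ``nan`` (missing) when every base in the interval is ambiguous.
    """
    seq = sequences[interval.chrom]
    if interval.end > len(seq):
        raise ValueError(
            f"interval [{interval.start}, {interval.end}) outside sequence of "
            f"length {len(seq)} on {interval.chrom}"
        )
    sub = str(seq[interval.start : interval.end]).upper()
    gc = sub.count("G") + sub.count("C")
    at = sub.count("A") + sub.count("T")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_bed(
    path: str | Path,
    cell_type: str = "",
    assay: str = "DHS",
    factor: str | None = None,
    factor_from_name: bool = False,
) -> list[Peak]:
    """Read a >=3-column BED file into :class:`Peak` records.

    Column 5 (if present) is read as the score; cell type and assay come from
    the caller since BED carries no such metadata.  For TFBS files the TF
    name can be taken per-peak from the BED name column
    (``factor_from_name=True``) or set globally via ``factor``.  Malformed
    lines raise with the offending line number.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            try:
                iv = GenomicInterval(fields[0], start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            score = 0.0
            if len(fields) >= 5 and fields[4] not in ("", "."):
                score = float(fields[4])
            fac = factor
            if factor_from_name and len(fields) >= 4 and fields[3] not in ("", "."):
                fac = fields[3]
            peaks.append(
                Peak(iv, score=score, cell_type=cell_type, assay=assay, factor=fac)
            )
    return peaks


def write_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as 5-column BED (name column holds the TF name if any)."""
    with open(path, "w") as fh:
        for p in peaks:
            name = p.factor if p.factor is not None else "."
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{name}\t{p.score:g}\n"
            )


class BedGraphTrack:
    """A sparse per-base signal track backed by bedGraph records.

    Records are (chrom, start, end, value) with 0-based half-open intervals;
    positions not covered by any record have value 0.  Records on the same
    chromosome must not overlap.
    """

    def __init__(self, records: Sequence[tuple[str, int, int, float]]):
        by_chrom: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
        for chrom, start, end, value in records:
            if end <= start or start < 0:
                raise ValueError(f"bad bedGraph interval [{start}, {end}) on {chrom}")
            by_chrom[chrom].append((start, end, float(value)))
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs])
            ends = np.array([r[1] for r in recs])
            vals = np.array([r[2] for r in recs])
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping bedGraph records on {chrom}")
            self._index[chrom] = (starts, ends, vals)

    @classmethod
    def from_path(cls, path: str | Path) -> "BedGraphTrack":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
        return cls(records)

    def records(self) -> list[tuple[str, int, int, float]]:
        out = []
        for chrom in sorted(self._index):
            starts, ends, vals = self._index[chrom]
            out.extend(
                (chrom, int(s), int(e), float(v))
                for s, e, v in zip(starts, ends, vals)
            )
        return out

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, value in self.records():
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Per-base mean of the track over ``[start, end)``; uncovered bases count as 0."""
        if end <= start:
            raise ValueError("empty interval")
        entry = self._index.get(chrom)
        if entry is None:
            return 0.0
        starts, ends, vals = entry
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(ov * vals[lo:hi]) / (end - start))


def load_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a chrom -> sequence-string mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_transcripts(
    annotation_path: str | Path,
    expression_path: str | Path | None = None,
    cell_types: Sequence[str] | None = None,
) -> list[TranscriptRecord]:
    """Read a transcript annotation TSV, optionally joining an expression matrix.

    The annotation is tab-delimited with a header and columns
    ``transcript_id, gene_id, chrom, strand, tss``.  The expression matrix is
    tab-delimited with transcript ids in the first column and one FPKM column
    per cell type; when ``cell_types`` is given the columns are reordered to
    match it.
    """
    import pandas as pd

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
    required = {"transcript_id", "gene_id", "chrom", "strand", "tss"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    expr = None
    if expression_path is not None:
        expr = pd.read_csv(expression_path, sep="\t", index_col=0)
        if cell_types is not None:
            expr = expr[list(cell_types)]
    records = []
    for row in ann.itertuples(index=False):
        vec = None
        if expr is not None and row.transcript_id in expr.index:
            vec = expr.loc[row.transcript_id].to_numpy(dtype=float)
        records.append(
            TranscriptRecord(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                tss=int(row.tss),
                expression=vec,
            )
        )
    return records


def read_mutations(path: str | Path) -> list[Mutation]:
    """Read a mutation TSV (``chrom, pos, ref, alt``; header required; 1-based pos)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise ValueError("mutation table must have 'chrom' and 'pos' columns")
    muts = []
    for row in df.itertuples(index=False):
        muts.append(
            Mutation(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=getattr(row, "ref", None),
                alt=getattr(row, "alt", None),
            )
        )
    return muts


def write_mutations(mutations: Sequence[Mutation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for m in mutations:
            fh.write(f"{m.chrom}\t{m.pos}\t{m.ref or '.'}\t{m.alt or '.'}\n")
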