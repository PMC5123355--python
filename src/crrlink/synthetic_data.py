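"""Synthetic regulatory landscapes with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage is testable without external downloads:

* a genome of several chromosomes carved into per-transcript slots, each
  holding a 200 kb candidate window centred on the TSS plus a flanking zone
  of low-scoring decoy DHS peaks;
* ~42 candidate CRRs per transcript (Poisson), of which 2 are planted true
  regulators whose DNase signal is correlated with a latent per-cell-type
  activity factor; decoy candidates get independent signals;
* expression generated from the linear model y = k0 + sum k_i log(1+s_i)
  plus Gaussian noise on the log scale, with a configurable fraction of
  negative (repressor) effects;
* somatic mutations whose per-CRR rates depend log-linearly on CRR length,
  GC content and replication timing, plus a functional-enrichment boost for
  true-regulator CRRs, and a uniform genomic background.

Everything is driven by a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crr_builder import crr_id_for
from .genomic_core import (
    BedGraphTrack,
    GenomicInterval,
    Mutation,
    Peak,
    TranscriptRecord,
    gc_fraction,
    write_bed,
    write_fasta,
    write_mutations,
)

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic landscape.

    Defaults mirror the scale of the real analysis: 14 cell types, a mean of
    42 candidate CRRs per transcript within the 100 kb window, 2 planted
    regulators per transcript of which 32% act as repressors, and a
    functional mutation-enrichment effect of 0.46 on the log-rate scale.
    """

    seed: int = 0
    n_cell_types: int = 14
    n_chromosomes: int = 2
    n_transcripts: int = 100
    chrom_length_bp: int | None = None  # computed from the slot layout if None
    window_bp: int = 100_000
    candidates_per_transcript_mean: float = 42.0
    n_true_regulators_per_transcript: int = 2
    effect_size_range: tuple[float, float] = (1.0, 2.0)
    repressor_fraction: float = 0.32
    noise_sd: float = 0.25
    latent_alpha: float = 0.6  # signal-vs-latent-activity correlation for true regulators
    crr_length_range: tuple[int, int] = (200, 800)
    decoys_per_dhs: int = 3  # low-scoring decoy DHS peaks per intended peak, per cell type
    n_background_dhs_per_cell: int = 10
    n_tf_factors: int = 8
    n_tf_cell_types: int = 5
    tfbs_fraction: float = 0.3
    mutation_rate_base: float = -6.6  # beta0 of the log-linear mutation-rate model
    beta_log_length: float = 1.0
    beta_replication_timing: float = -0.3
    beta_gc: float = 0.8
    functional_enrichment_delta: float = 0.46
    background_mutation_rate_per_bp: float = 2e-6
    slot_margin_bp: int = 10_000

    def __post_init__(self) -> None:
        if min(self.n_cell_types, self.n_chromosomes) < 1 or self.n_transcripts < 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.repressor_fraction <= 1:
            raise ValueError("repressor_fraction must lie in [0, 1]")

    @property
    def slot_bp(self) -> int:
        return 2 * self.window_bp + self.slot_margin_bp

    def cell_types(self) -> tuple[str, ...]:
        return tuple(f"CT{i + 1:02d}" for i in range(self.n_cell_types))


@dataclass
class SyntheticTruth:
    """Planted ground truth: regulators and coefficients per transcript, the
    functional flag and the realized mutation rate per CRR."""

    regulator_ids: dict[str, tuple[str, ...]] = field(default_factory=dict)
    candidate_ids: dict[str, tuple[str, ...]] = field(default_factory=dict)
    coefficients: dict[str, dict[str, float]] = field(default_factory=dict)
    intercepts: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    functional_crrs: set[str] = field(default_factory=set)
    mutation_rates: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regulator_ids": {k: list(v) for k, v in self.regulator_ids.items()},
            "candidate_ids": {k: list(v) for k, v in self.candidate_ids.items()},
            "coefficients": self.coefficients,
            "intercepts": self.intercepts,
            "noise_sd": self.noise_sd,
            "functional_crrs": sorted(self.functional_crrs),
            "mutation_rates": self.mutation_rates,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticLandscape:
    """In-memory synthetic data set; ``write`` serialises it to standard formats."""

    config: SimulationConfig
    cell_types: tuple[str, ...]
    sequences: dict[str, str]
    transcripts: list[TranscriptRecord]
    tfbs_peaks: list[Peak]
    dhs_peaks: list[Peak]
    h3k27ac_peaks: list[Peak]
    signal_tracks: dict[str, BedGraphTrack]
    replication_timing: BedGraphTrack
    intended_crrs: list[GenomicInterval]
    signal_by_crr: dict[str, np.ndarray]
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "genome.fa")
        for ct in self.cell_types:
            write_bed(
                [p for p in self.dhs_peaks if p.cell_type == ct],
                outdir / f"dhs_{ct}.bed",
            )
            tf = [p for p in self.tfbs_peaks if p.cell_type == ct]
            if tf:
                write_bed(tf, outdir / f"tfbs_{ct}.bed")
            h3k = [p for p in self.h3k27ac_peaks if p.cell_type == ct]
            if h3k:
                write_bed(h3k, outdir / f"h3k27ac_{ct}.bed")
            self.signal_tracks[ct].write(outdir / f"signal_{ct}.bedgraph")
        self.replication_timing.write(outdir / "replication_timing.bedgraph")
        ann = pd.DataFrame(
            {
                "transcript_id": [t.transcript_id for t in self.transcripts],
                "gene_id": [t.gene_id for t in self.transcripts],
                "chrom": [t.chrom for t in self.transcripts],
                "strand": [t.strand for t in self.transcripts],
                "tss": [t.tss for t in self.transcripts],
            }
        )
        ann.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        if self.transcripts and self.transcripts[0].expression is not None:
            expr = pd.DataFrame(
                [t.expression for t in self.transcripts],
                index=[t.transcript_id for t in self.transcripts],
                columns=list(self.cell_types),
            )
            expr.index.name = "transcript_id"
            expr.to_csv(outdir / "expression.tsv", sep="\t")
        self.truth.to_json(outdir / "truth.json")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    # inverse-CDF sampling on uint8 draws (GC resolution 1/256, plenty for
    # composition covariates measured from the realized sequence)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    t = np.round(np.cumsum(p)[:-1] * 256).astype(np.int32)
    draws = rng.integers(0, 256, size=length, dtype=np.uint16)
    code = (draws >= t[0]).astype(np.uint8)
    code += draws >= t[1]
    code += draws >= t[2]
    return code


def _partition_starts(
    rng: np.random.Generator, zone_start: int, zone_bp: int, lengths: np.ndarray
) -> np.ndarray:
    """Place intervals of the given lengths inside a zone without overlap."""
    free = zone_bp - int(lengths.sum())
    if free <= 0:
        raise ValueError(
            f"infeasible packing: {lengths.sum()} bp of intervals in a {zone_bp} bp zone"
        )
    cuts = np.sort(rng.random(len(lengths))) * free
    offsets = np.concatenate(([0], np.cumsum(lengths[:-1])))
    return zone_start + (cuts + offsets).astype(int)


def simulate_landscape(config: SimulationConfig) -> SyntheticLandscape:
    """Generate the full synthetic landscape (no expression or mutations yet)."""
    rng = np.random.default_rng(config.seed)
    cell_types = config.cell_types()
    n_slots_per_chrom = (
        max(1, math.ceil(config.n_transcripts / config.n_chromosomes))
        if config.n_transcripts
        else 1
    )
    slots_bp = n_slots_per_chrom * config.slot_bp
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    lo, hi = config.crr_length_range
    transcripts: list[TranscriptRecord] = []
    intended: list[GenomicInterval] = []
    crr_gc_target: dict[str, float] = {}
    signal_by_crr: dict[str, np.ndarray] = {}
    dhs_peaks: list[Peak] = []
    tfbs_peaks: list[Peak] = []
    h3k27ac_peaks: list[Peak] = []
    truth = SyntheticTruth(noise_sd=config.noise_sd)
    dhs_cell_counts = np.zeros(config.n_cell_types, dtype=int)
    alpha = config.latent_alpha

    for ti in range(config.n_transcripts):
        chrom = chroms[ti % config.n_chromosomes]
        slot_idx = ti // config.n_chromosomes
        slot_start = slot_idx * config.slot_bp
        window_start = slot_start
        tss = window_start + config.window_bp
        tid = f"TX{ti + 1:05d}"
        transcripts.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=f"G{ti + 1:05d}",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                tss=tss,
            )
        )
        n_cand = max(
            config.n_true_regulators_per_transcript,
            int(rng.poisson(config.candidates_per_transcript_mean)),
        )
        lengths = rng.integers(lo, hi + 1, size=n_cand)
        starts = _partition_starts(rng, window_start, 2 * config.window_bp, lengths)
        ivs = [
            GenomicInterval(chrom, int(s), int(s + l))
            for s, l in zip(starts, lengths)
        ]
        ids = [crr_id_for(iv) for iv in ivs]
        intended.extend(ivs)
        truth.candidate_ids[tid] = tuple(ids)
        for cid in ids:
            crr_gc_target[cid] = rng.uniform(0.30, 0.70)

        # planted regulators and their coefficients
        reg_idx = rng.choice(n_cand, config.n_true_regulators_per_transcript, replace=False)
        reg_idx = np.sort(reg_idx)
        signs = np.where(
            rng.random(len(reg_idx)) < config.repressor_fraction, -1.0, 1.0
        )
        mags = rng.uniform(*config.effect_size_range, size=len(reg_idx))
        ks = signs * mags
        truth.regulator_ids[tid] = tuple(ids[i] for i in reg_idx)
        truth.coefficients[tid] = {
            ids[i]: float(k) for i, k in zip(reg_idx, ks)
        }
        truth.functional_crrs.update(ids[i] for i in reg_idx)

        # per-cell-type log-signals: true regulators load on a latent
        # activity factor of the transcript, with the loading sign matching
        # their effect sign (enhancers active with the gene, repressors
        # anti-correlated); decoys are independent noise
        latent = rng.standard_normal(config.n_cell_types)
        mu = rng.uniform(1.5, 3.0, size=n_cand)
        eps = rng.standard_normal((n_cand, config.n_cell_types))
        x = mu[:, None] + eps
        x[reg_idx] = (
            mu[reg_idx, None]
            + np.sign(ks)[:, None] * alpha * latent[None, :]
            + math.sqrt(1 - alpha**2) * eps[reg_idx]
        )
        x = np.maximum(x, 0.0)
        # intercept chosen so the regulator contribution is centred: mean
        # log-expression sits near the base level instead of drifting with
        # the effect signs, keeping expm1(y) in a realistic FPKM range
        truth.intercepts[tid] = float(rng.uniform(3.0, 5.0) - ks @ mu[reg_idx])
        s = np.expm1(x)
        for i, cid in enumerate(ids):
            signal_by_crr[cid] = s[i]

        # peaks: one DHS per intended CRR in a random cell type, H3K27ac over
        # it, TFBS inside a fraction of CRRs (confined to the TF cell types)
        for i, iv in enumerate(ivs):
            ct_i = int(rng.integers(config.n_cell_types))
            dhs_cell_counts[ct_i] += 1
            dhs_peaks.append(
                Peak(iv, score=float(rng.uniform(10, 100)), cell_type=cell_types[ct_i], assay="DHS")
            )
            mark_iv = GenomicInterval(chrom, max(0, iv.start - 50), iv.end + 50)
            h3k27ac_peaks.append(
                Peak(
                    mark_iv,
                    score=float(rng.uniform(1, 10)),
                    cell_type=cell_types[int(rng.integers(config.n_cell_types))],
                    assay="H3K27ac",
                )
            )
            if rng.random() < config.tfbs_fraction and iv.length >= 40:
                for _ in range(int(rng.integers(1, 3))):
                    off = int(rng.integers(0, iv.length - 20))
                    w = int(rng.integers(10, min(200, iv.length - off) + 1))
                    tfbs_peaks.append(
                        Peak(
                            GenomicInterval(chrom, iv.start + off, iv.start + off + w),
                            score=float(rng.uniform(1, 100)),
                            cell_type=cell_types[int(rng.integers(config.n_tf_cell_types))],
                            assay="TFBS",
                            factor=f"TF{int(rng.integers(config.n_tf_factors)) + 1}",
                        )
                    )

    # decoy DHS peaks with strictly lower scores than intended peaks, packed
    # into an intergenic tail after the transcript slots; per-cell-type
    # top-25% selection then retains the intended peaks, and the H3K27ac
    # filter removes any decoy that squeezes through the ceil() rounding
    decoys: list[tuple[int, int]] = []  # (cell-type index, length)
    for ci, n_int in enumerate(dhs_cell_counts):
        n_decoy = config.decoys_per_dhs * int(n_int) + config.n_background_dhs_per_cell
        decoys.extend(
            (ci, int(l)) for l in rng.integers(lo, hi + 1, size=n_decoy)
        )
    rng.shuffle(decoys)
    per_chrom_decoys = np.array_split(np.arange(len(decoys)), config.n_chromosomes)
    chrom_len: dict[str, int] = {}
    for chrom_i, idxs in enumerate(per_chrom_decoys):
        chrom = chroms[chrom_i]
        tail_start = slots_bp + config.slot_margin_bp
        lengths = np.array([decoys[i][1] for i in idxs], dtype=int)
        tail_bp = 2 * int(lengths.sum()) + 20_000
        chrom_len[chrom] = tail_start + tail_bp + config.slot_margin_bp
        if (
            config.chrom_length_bp is not None
            and chrom_len[chrom] > config.chrom_length_bp
        ):
            raise ValueError(
                f"infeasible packing: need {chrom_len[chrom]} bp on {chrom}, "
                f"have {config.chrom_length_bp}"
            )
        if config.chrom_length_bp is not None:
            chrom_len[chrom] = config.chrom_length_bp
        if len(idxs) == 0:
            continue
        starts = _partition_starts(rng, tail_start, tail_bp, lengths)
        for i, s in zip(idxs, starts):
            ci, l = decoys[i]
            dhs_peaks.append(
                Peak(
                    GenomicInterval(chrom, int(s), int(s + l)),
                    score=float(rng.uniform(0.1, 9.0)),
                    cell_type=cell_types[ci],
                    assay="DHS",
                )
            )

    # replication timing: a smooth wave along each chromosome, 10 kb steps
    rt_records = []
    phases = rng.uniform(0, 2 * np.pi, size=config.n_chromosomes)
    for ci, chrom in enumerate(chroms):
        L = chrom_len[chrom]
        edges = np.arange(0, L + 10_000, 10_000)
        mids = (edges[:-1] + np.minimum(edges[1:], L)) / 2
        vals = np.sin(2 * np.pi * mids / 2_000_000 + phases[ci])
        rt_records.extend(
            (chrom, int(s), int(min(e, L)), float(v))
            for s, e, v in zip(edges[:-1], edges[1:], vals)
            if s < L
        )
    rt_track = BedGraphTrack(rt_records)

    # genome sequence: background GC 0.40, per-CRR target GC in [0.30, 0.70]
    sequences: dict[str, str] = {}
    seq_arrays = {
        chrom: _random_sequence(rng, chrom_len[chrom], 0.40) for chrom in chroms
    }
    for iv in intended:
        arr = seq_arrays[iv.chrom]
        arr[iv.start : iv.end] = _random_sequence(
            rng, iv.length, crr_gc_target[crr_id_for(iv)]
        )
    for chrom, arr in seq_arrays.items():
        sequences[chrom] = _BASES[arr].tobytes().decode("ascii")

    signal_tracks = {
        ct: BedGraphTrack(
            [
                (iv.chrom, iv.start, iv.end, signal_by_crr[crr_id_for(iv)][j])
                for iv in intended
            ]
        )
        for j, ct in enumerate(cell_types)
    }
    logger.info(
        "simulated %d transcripts, %d candidate CRRs, %d DHS peaks on %d chromosomes",
        config.n_transcripts,
        len(intended),
        len(dhs_peaks),
        config.n_chromosomes,
    )
    return SyntheticLandscape(
        config=config,
        cell_types=cell_types,
        sequences=sequences,
        transcripts=transcripts,
        tfbs_peaks=tfbs_peaks,
        dhs_peaks=dhs_peaks,
        h3k27ac_peaks=h3k27ac_peaks,
        signal_tracks=signal_tracks,
        replication_timing=rt_track,
        intended_crrs=intended,
        signal_by_crr=signal_by_crr,
        truth=truth,
    )


def simulate_expression(landscape: SyntheticLandscape) -> pd.DataFrame:
    """Generate expression from the planted linear model, in place.

    For each transcript, ``y_c = k0 + sum_i k_i log(1 + s_ic) + N(0, noise_sd)``
    per cell type, then ``FPKM = exp(y) - 1`` floored at 0.  Returns the
    transcripts-by-cell-types FPKM matrix and fills ``transcript.expression``.
    """
    config = landscape.config
    rng = np.random.default_rng([config.seed, 1])
    rows = {}
    for t in landscape.transcripts:
        tid = t.transcript_id
        y = np.full(config.n_cell_types, landscape.truth.intercepts[tid])
        for cid, k in landscape.truth.coefficients[tid].items():
            y = y + k * np.log1p(landscape.signal_by_crr[cid])
        y = y + rng.normal(0, config.noise_sd, size=config.n_cell_types)
        fpkm = np.maximum(np.expm1(y), 0.0)
        t.expression = fpkm
        rows[tid] = fpkm
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(landscape.cell_types)
    )


def mutation_rates(
    length_bp: np.ndarray,
    replication_timing: np.ndarray,
    gc: np.ndarray,
    functional: np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Per-CRR expected mutation counts under the log-linear rate model."""
    eta = (
        config.mutation_rate_base
        + config.beta_log_length * np.log(length_bp)
        + config.beta_replication_timing * replication_timing
        + config.beta_gc * gc
        + config.functional_enrichment_delta * functional.astype(float)
    )
    return np.exp(eta)


def simulate_mutation_counts(
    covariates: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Poisson counts from a covariate table with columns
    ``length_bp, replication_timing, gc, functional``."""
    rates = mutation_rates(
        covariates["length_bp"].to_numpy(dtype=float),
        covariates["replication_timing"].to_numpy(dtype=float),
        covariates["gc"].to_numpy(dtype=float),
        covariates["functional"].to_numpy(),
        config,
    )
    return rng.poisson(rates)


def simulate_crr_covariate_table(
    n: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    frac_functional: float = 0.15,
) -> pd.DataFrame:
    """A standalone covariate table (no genome needed) for count-model studies.

    The ``chosen`` column equals the planted functional flag, so the table
    represents the ideal case where model selection found exactly the
    functional CRRs.
    """
    lo, hi = config.crr_length_range
    df = pd.DataFrame(
        {
            "length_bp": rng.integers(lo, hi + 1, size=n),
            "replication_timing": rng.uniform(-1, 1, size=n),
            "gc": rng.uniform(0.30, 0.70, size=n),
            "functional": rng.random(n) < frac_functional,
            "nearest_tss_distance": rng.integers(0, 100_000, size=n),
        }
    )
    df["chosen"] = df["functional"]
    df["mutation_count"] = simulate_mutation_counts(df, config, rng)
    return df


def simulate_mutations(landscape: SyntheticLandscape) -> list[Mutation]:
    """Draw the somatic-mutation catalogue for a landscape.

    CRR counts are Poisson with the log-linear covariate rates (using the GC
    and replication timing actually measurable from the generated genome);
    positions are uniform within each CRR, 1-based on output.  A uniform
    genomic background at ``background_mutation_rate_per_bp`` is added so
    mutations also fall outside CRRs.  Realized rates land in
    ``landscape.truth.mutation_rates``.
    """
    config = landscape.config
    rng = np.random.default_rng([config.seed, 2])
    funcs = landscape.truth.functional_crrs
    ivs = landscape.intended_crrs
    if ivs:
        length = np.array([iv.length for iv in ivs], dtype=float)
        gc = np.array([gc_fraction(iv, landscape.sequences) for iv in ivs])
        rt = np.array(
            [
                landscape.replication_timing.mean(iv.chrom, iv.start, iv.end)
                for iv in ivs
            ]
        )
        functional = np.array([crr_id_for(iv) in funcs for iv in ivs])
        rates = mutation_rates(length, rt, gc, functional, config)
    else:
        rates = np.array([])
    muts: list[Mutation] = []
    for iv, rate in zip(ivs, rates):
        landscape.truth.mutation_rates[crr_id_for(iv)] = float(rate)
        n = rng.poisson(rate)
        for pos0 in rng.integers(iv.start, iv.end, size=n):
            muts.append(Mutation(chrom=iv.chrom, pos=int(pos0) + 1))
    for chrom, seq in landscape.sequences.items():
        n_bg = rng.poisson(config.background_mutation_rate_per_bp * len(seq))
        for pos0 in rng.integers(0, len(seq), size=n_bg):
            muts.append(Mutation(chrom=chrom, pos=int(pos0) + 1))
    muts.sort(key=lambda m: (m.chrom, m.pos))
    return muts
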