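"""Convenience driver: run the complete analysis on a synthetic landscape.

Chains the pipeline stages — simulate, build CRRs, fit expression models,
permutation significance, mutation mapping, enrichment — with the library
defaults, either fully in memory or through the on-disk TSV/BED formats
(exercising every reader and writer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .crr_builder import CRR, BuildConfig, attach_covariates, attach_signal, build_crrs
from .enrichment import EnrichmentResult, GLMFit, fit_mutation_glm, stratified_reports
from .expression_models import (
    ExpressionModel,
    ModelConfig,
    candidates_for,
    design_matrix,
    filter_transcripts,
    fit_all_models,
)
from .genomic_core import Mutation
from .mutation_map import build_mutation_stats
from .significance import PermutationNull, attach_significance
from .synthetic_data import (
    SimulationConfig,
    SyntheticLandscape,
    simulate_expression,
    simulate_landscape,
    simulate_mutations,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    landscape: SyntheticLandscape
    mutations: list[Mutation]
    crrs: list[CRR]
    models: list[ExpressionModel]
    null: PermutationNull | None
    stats: pd.DataFrame
    reports: dict[str, EnrichmentResult | None]
    glm: GLMFit


def run_synthetic_analysis(
    sim_config: SimulationConfig,
    model_config: ModelConfig | None = None,
    n_perm: int = 100,
    n_per_stratum: int = 4,
    significance_seed: int = 0,
    roundtrip_dir: str | Path | None = None,
) -> AnalysisResult:
    """Simulate a landscape and run the full chosen-vs-rejected analysis.

    When ``roundtrip_dir`` is given, all simulated data are first written to
    disk and read back through the standard-format readers, so the analysis
    runs on the parsed files rather than the in-memory objects.
    """
    model_config = model_config or ModelConfig()
    landscape = simulate_landscape(sim_config)
    simulate_expression(landscape)
    mutations = simulate_mutations(landscape)

    if roundtrip_dir is not None:
        from .genomic_core import (
            BedGraphTrack,
            load_fasta,
            read_bed,
            read_mutations,
            read_transcripts,
            write_mutations,
        )

        outdir = Path(roundtrip_dir)
        landscape.write(outdir)
        write_mutations(mutations, outdir / "mutations.tsv")
        cell_types = landscape.cell_types
        sequences = load_fasta(outdir / "genome.fa")
        tfbs, dhs, h3k = [], [], []
        for ct in cell_types:
            dhs.extend(read_bed(outdir / f"dhs_{ct}.bed", cell_type=ct, assay="DHS"))
            p = outdir / f"tfbs_{ct}.bed"
            if p.exists():
                tfbs.extend(
                    read_bed(p, cell_type=ct, assay="TFBS", factor_from_name=True)
                )
            p = outdir / f"h3k27ac_{ct}.bed"
            if p.exists():
                h3k.extend(read_bed(p, cell_type=ct, assay="H3K27ac"))
        tracks = {
            ct: BedGraphTrack.from_path(outdir / f"signal_{ct}.bedgraph")
            for ct in cell_types
        }
        rt = BedGraphTrack.from_path(outdir / "replication_timing.bedgraph")
        transcripts = read_transcripts(
            outdir / "annotation.tsv", outdir / "expression.tsv", cell_types
        )
        mutations = read_mutations(outdir / "mutations.tsv")
    else:
        sequences = landscape.sequences
        tfbs, dhs, h3k = (
            landscape.tfbs_peaks,
            landscape.dhs_peaks,
            landscape.h3k27ac_peaks,
        )
        tracks = landscape.signal_tracks
        rt = landscape.replication_timing
        transcripts = landscape.transcripts
        cell_types = landscape.cell_types

    build_config = BuildConfig(cell_types=tuple(cell_types))
    crrs = build_crrs(tfbs, dhs, h3k, build_config)
    crrs = attach_signal(crrs, tracks, build_config)
    crrs = attach_covariates(crrs, sequences, rt)

    models = fit_all_models(transcripts, crrs, model_config)
    null = None
    if n_perm > 0:
        kept = {
            t.transcript_id: t for t in filter_transcripts(transcripts, model_config)
        }
        data = {
            m.transcript_id: design_matrix(
                kept[m.transcript_id],
                candidates_for(kept[m.transcript_id], crrs, model_config),
                model_config,
            )
            for m in models
        }
        null = attach_significance(
            models,
            data,
            n_perm=n_perm,
            n_per_stratum=n_per_stratum,
            seed=significance_seed,
            config=model_config,
        )

    stats = build_mutation_stats(crrs, models, transcripts, mutations)
    reports = stratified_reports(stats, models)
    glm = fit_mutation_glm(stats)
    return AnalysisResult(
        landscape=landscape,
        mutations=mutations,
        crrs=crrs,
        models=models,
        null=null,
        stats=stats,
        reports=reports,
        glm=glm,
    )
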