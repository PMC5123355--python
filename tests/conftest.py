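"""Shared fixtures: a small planted landscape run through the whole pipeline."""

import warnings

import numpy as np
import pytest

import crrlink as cl
from crrlink.expression_models import ModelConfig, candidates_for, design_matrix

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_landscape():
    """40 transcripts with planted effects, expression and mutations drawn."""
    cfg = cl.SimulationConfig(seed=42, n_transcripts=40)
    land = cl.simulate_landscape(cfg)
    cl.simulate_expression(land)
    muts = cl.simulate_mutations(land)
    return land, muts


@pytest.fixture(scope="session")
def small_pipeline(small_landscape):
    """CRRs, fitted models, design matrices and the mutation-stats table."""
    land, muts = small_landscape
    bc = cl.BuildConfig(cell_types=land.cell_types)
    crrs = cl.build_crrs(land.tfbs_peaks, land.dhs_peaks, land.h3k27ac_peaks, bc)
    crrs = cl.attach_signal(crrs, land.signal_tracks, bc)
    crrs = cl.attach_covariates(crrs, land.sequences, land.replication_timing)
    mc = ModelConfig()
    models = cl.fit_all_models(land.transcripts, crrs, mc)
    kept = {t.transcript_id: t for t in cl.filter_transcripts(land.transcripts, mc)}
    data = {
        m.transcript_id: design_matrix(
            kept[m.transcript_id], candidates_for(kept[m.transcript_id], crrs, mc), mc
        )
        for m in models
    }
    stats = cl.build_mutation_stats(crrs, models, land.transcripts, muts)
    return {
        "landscape": land,
        "mutations": muts,
        "build_config": bc,
        "model_config": mc,
        "crrs": crrs,
        "models": models,
        "data": data,
        "stats": stats,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
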