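"""Shared fixtures: synthetic cohorts at desk scale, built once per session."""

import numpy as np
import pytest

import marrowatlas as ma

# thresholds suited to the synthetic scale (250-300 genes, ~2k UMIs/cell)
SYN_QC = ma.QCThresholds(min_umi=200, min_genes=50, max_mito_fraction=0.2,
                         min_cells_per_sample=50)


def _prepare(ds):
    kept, _ = ma.qc_filter(ds, SYN_QC)
    return ma.normalize_total(kept)


@pytest.fixture(scope="session")
def ref_cfg():
    return ma.CohortConfig(n_studies=2, samples_per_study=6, n_genes=250,
                           mean_cells_per_sample=120, seed=7)


@pytest.fixture(scope="session")
def ref_data(ref_cfg):
    return ma.generate_reference(ref_cfg)


@pytest.fixture(scope="session")
def ref_norm(ref_data):
    ds, _ = ref_data
    return _prepare(ds)


@pytest.fixture(scope="session")
def atlas(ref_norm):
    return ma.build_reference(ref_norm, per_sample_n=200, consensus_n=200,
                              seed=1)


@pytest.fixture(scope="session")
def query_bundle(ref_cfg, atlas):
    """Query with 30% of memT cells carrying a large 50-gene shift."""
    q, truth = ma.generate_query(ref_cfg, n_samples=4, abnormal_fraction=0.3,
                                 shift_magnitude=5.0,
                                 shifted_cell_type="memT", seed=11)
    qn = _prepare(q)
    q_emb, result = ma.map_query(atlas, qn, seed=3)
    return {"query": qn, "truth": truth, "embedding": q_emb, "result": result}


@pytest.fixture(scope="session")
def screen_cohort():
    """40-sample cohort (2 studies x 20) for the age-gene screen."""
    cfg = ma.CohortConfig(n_studies=2, samples_per_study=20, n_genes=300,
                          mean_cells_per_sample=150, seed=21)
    ds, truth = ma.generate_reference(cfg)
    kept = _prepare(ds)
    pb = ma.pseudobulk(kept)
    pbc = ma.remove_study_effects(pb, kept.sample_table)
    ages = dict(zip(kept.sample_table["sample_id"],
                    kept.sample_table["age_years"]))
    return {"cfg": cfg, "ds": kept, "truth": truth, "pb": pb, "pbc": pbc,
            "ages": ages}


@pytest.fixture(scope="session")
def clock_cohort():
    """60-sample cohort (3 studies x 20) for clock training/evaluation."""
    cfg = ma.CohortConfig(n_studies=3, samples_per_study=20, n_genes=300,
                          mean_cells_per_sample=150, seed=33)
    ds, truth = ma.generate_reference(cfg)
    kept = _prepare(ds)
    pb = ma.remove_study_effects(ma.pseudobulk(kept), kept.sample_table)
    ages = dict(zip(kept.sample_table["sample_id"],
                    kept.sample_table["age_years"]))
    agt = ma.age_correlation(pb, ages)
    return {"cfg": cfg, "ds": kept, "truth": truth, "pb": pb, "ages": ages,
            "age_genes": agt}
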