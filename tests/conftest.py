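"""Shared fixtures.

The heavyweight fixture is ``replicate_summaries``: ten seeded end-to-end
runs of the synthetic pipeline at default scenario settings, summarised
once per session and reused by the acceptance tests and the end-to-end
property tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sccmap.containers import CountMatrix
from sccmap.pipeline import run_synthetic_pipeline
from sccmap.synthetic import SimScenario, simulate_counts

N_REPLICATES = 10
REPLICATE_SEEDS = tuple(range(1, N_REPLICATES + 1))


@pytest.fixture(scope="session")
def small_scenario() -> SimScenario:
    """A fast, fully separable scenario for unit tests."""
    return SimScenario(
        n_cell_types=3, cells_per_type=(250, 200, 150), n_genes=1200,
        disease_cluster_size=40, program_size=40, type_de_genes=60,
        qc_fail_fraction=0.05, seed=42)


@pytest.fixture(scope="session")
def small_sample(small_scenario):
    return simulate_counts(small_scenario)


def _summarise(res) -> dict:
    lab = res.clusters_disease.labels
    cells = res.truth.cells
    disease_cells = cells[cells.is_disease
                          & cells.cell_id.isin(lab.index)].cell_id
    vc = lab.loc[disease_cells].value_counts()
    modal_cluster = vc.index[0]
    out = {
        "modal_fraction": float(vc.iloc[0] / len(disease_cells)),
        "modal_cluster": modal_cluster,
        "identified": res.identification.identified,
        "identified_correctly": (res.identification.identified
                                 and res.identification.cluster_label
                                 == modal_cluster),
        "planted_moa_rank": None,
        "planted_moa_fdr": None,
        "attenuation_fraction": None,
        "cas_planted_fraction": None,
        "planted_mean_r": None,
        "noise_mean_r": None,
    }
    if res.moa_table is not None:
        planted = "MTOR inhibitor"
        moas = list(res.moa_table["moa"])
        out["planted_moa_rank"] = moas.index(planted)
        out["planted_moa_fdr"] = float(
            res.moa_table.set_index("moa").loc[planted, "fdr"])
        prog = [g for g in res.truth.program_genes
                if g in res.dcs.table.index and g in res.pseudobulk.table.index]
        out["attenuation_fraction"] = float(
            (res.pseudobulk.table.loc[prog, "lfc"].abs()
             < res.dcs.table.loc[prog, "lfc"].abs()).mean())
        planted_genes = set(res.truth.program_genes) | set(res.truth.marker_genes)
        cas = set(res.disease_cas_genes or [])
        out["cas_planted_fraction"] = len(planted_genes & cas) / len(planted_genes)
        is_planted = res.library_truth.set_index("signature_id")["is_planted"]
        r = res.connectivity["r"]
        out["planted_mean_r"] = float(r[is_planted.loc[r.index]].mean())
        out["noise_mean_r"] = float(r[~is_planted.loc[r.index]].mean())
    return out


@pytest.fixture(scope="session")
def pipeline_result():
    """One full pipeline run at default settings (seed 1), kept whole."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_synthetic_pipeline(seed=REPLICATE_SEEDS[0])


@pytest.fixture(scope="session")
def replicate_summaries(pipeline_result) -> list[dict]:
    """Summaries of ten seeded end-to-end runs at default settings."""
    summaries = [_summarise(pipeline_result)]
    for seed in REPLICATE_SEEDS[1:]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summaries.append(_summarise(run_synthetic_pipeline(seed=seed)))
    return summaries


def toy_matrix(counts: np.ndarray, gene_ids=None, mito: int = 0) -> CountMatrix:
    """Dense array -> CountMatrix; first ``mito`` genes get MT- names."""
    counts = np.asarray(counts)
    g, c = counts.shape
    if gene_ids is None:
        gene_ids = [f"MT-{i}" if i < mito else f"g{i}" for i in range(g)]
    return CountMatrix(sp.csr_matrix(counts), np.array(gene_ids, dtype=object),
                       np.array([f"cell{j}" for j in range(c)], dtype=object),
                       sample_label="toy")
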