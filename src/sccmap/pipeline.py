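"""End-to-end driver: simulate -> cluster -> CAS -> identify -> match ->
DCS -> connectivity -> MOA enrichment.

Intended for synthetic benchmarking and as the reference wiring of the
individual stages; each stage is equally usable on its own with real data
loaded through the containers' readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .connectivity import correlate_library, select_query_genes
from .containers import CountMatrix
from .disease import (DiseaseSignature, build_dcs, build_pseudobulk_signature)
from .moa import enrich_all_moas
from .population import (IdentificationResult, MatchResult,
                         identify_disease_cluster, match_control_clusters)
from .preprocess import cluster_sample
from .signatures import build_cluster_signatures
from .synthetic import (LibScenario, SimScenario, landmark_panel,
                        simulate_library, simulate_sample_pair)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    clusters_disease: object
    clusters_control: object
    identification: IdentificationResult
    match: MatchResult | None
    dcs: DiseaseSignature | None
    pseudobulk: DiseaseSignature | None
    connectivity: pd.DataFrame | None
    moa_table: pd.DataFrame | None
    truth: object = None
    library_truth: pd.DataFrame | None = None
    disease_cas_genes: list | None = None

    @property
    def top_moa(self) -> str | None:
        if self.moa_table is None or self.moa_table.empty:
            return None
        return self.moa_table.iloc[0]["moa"]


def run_synthetic_pipeline(sim: SimScenario | None = None,
                           lib: LibScenario | None = None,
                           seed: int = 0, engine: str = "hurdle",
                           resolution: float = 0.8,
                           n_landmarks: int | None = None,
                           compute_pseudobulk: bool = True
                           ) -> PipelineResult:
    """Run the whole protocol on one simulated disease/control sample pair.

    ``seed`` reseeds both scenario objects (count sampling, library noise,
    clustering). The marker panel handed to the identification stage is the
    scenario's planted panel — the pipeline input a practitioner would take
    from the literature; cluster-level truth labels are only returned for
    external evaluation, never consumed.
    """
    sim = replace(sim or SimScenario(), seed=seed)
    lib = replace(lib or LibScenario(), seed=seed)
    m_dis, m_ctl, truth = simulate_sample_pair(sim)

    filt_d, normed_d, clus_d = cluster_sample(m_dis, resolution=resolution,
                                              seed=seed)
    filt_c, normed_c, clus_c = cluster_sample(m_ctl, resolution=resolution,
                                              seed=seed)
    logger.info("clusters: disease %d, control %d",
                clus_d.n_clusters, clus_c.n_clusters)

    sigs_d = build_cluster_signatures(normed_d, filt_d.gene_ids, clus_d,
                                      engine=engine)
    sigs_c = build_cluster_signatures(normed_c, filt_c.gene_ids, clus_c,
                                      engine=engine)

    ident = identify_disease_cluster(sigs_d, truth.marker_genes)
    if not ident.identified:
        return PipelineResult(clus_d, clus_c, ident, None, None, None, None,
                              None, truth=truth)
    disease_label = ident.cluster_label

    match = match_control_clusters(sigs_d[disease_label], sigs_c)
    disease_cells = filt_d.cells_by_id(clus_d.cells_of(disease_label))
    control_ids = np.concatenate(
        [clus_c.cells_of(lbl) for lbl in match.selected_control_clusters])
    control_cells = filt_c.cells_by_id(control_ids)

    dcs = build_dcs(disease_cells, control_cells, engine=engine)
    pseudo = (build_pseudobulk_signature(filt_d, filt_c, engine=engine)
              if compute_pseudobulk else None)

    landmarks = landmark_panel(truth, m_dis.gene_ids,
                               n=n_landmarks or lib.n_landmark_genes,
                               seed=seed)
    program_vec = truth.program_lfc.reindex(landmarks).fillna(0.0)
    library, lib_truth = simulate_library(
        replace(lib, n_landmark_genes=len(landmarks)), program_vec)

    query = select_query_genes(dcs, library.landmark_genes)
    conn = correlate_library(query, library)
    moa_table = enrich_all_moas(conn, library.metadata)
    return PipelineResult(clus_d, clus_c, ident, match, dcs, pseudo, conn,
                          moa_table, truth=truth, library_truth=lib_truth,
                          disease_cas_genes=list(sigs_d[disease_label].cas_genes))
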