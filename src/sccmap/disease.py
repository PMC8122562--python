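"""Disease-characterizing signature (DCS), pseudo-bulk contrast, and ORA.

The DCS contrasts the cells of the identified disease cluster with the
pooled cells of the matched control clusters. The pseudo-bulk signature
contrasts all cells of the disease sample with all cells of the control
sample, mimicking bulk RNA-seq; because the disease population is rare,
its program is diluted in the pseudo-bulk contrast — the motivation for
working at cluster resolution.

Functional annotation of a signature's top up-regulated genes is a generic
gene-set over-representation analysis (ORA) against any user-supplied GMT
collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from gseapy.parser import read_gmt as _gseapy_read_gmt

from .containers import CountMatrix
from .de import de_between
from .population import fisher_enrichment, _enrichment_table
from .preprocess import concatenate, log_normalize
from .signatures import pi_score


@dataclass
class DiseaseSignature:
    """Per-gene lfc / p / fdr / pi for disease cells vs reference cells."""

    table: pd.DataFrame  # index gene; lfc, p_value, fdr, pi
    provenance: dict = field(default_factory=dict)

    def top_up_genes(self, n: int = 200, alpha: float = 0.05) -> list:
        """The n most significant up-regulated genes at FDR < alpha."""
        return _top_genes(self.table, n, alpha, direction=+1)

    def top_down_genes(self, n: int = 200, alpha: float = 0.05) -> list:
        return _top_genes(self.table, n, alpha, direction=-1)

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiseaseSignature":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, {"source": str(path)})


def _top_genes(table: pd.DataFrame, n: int, alpha: float, direction: int
               ) -> list:
    sub = table[(np.sign(table["lfc"]) == direction) & (table["fdr"] < alpha)]
    key = pd.DataFrame({
        "fdr": sub["fdr"].to_numpy(), "p": sub["p_value"].to_numpy(),
        "lfc": -direction * sub["lfc"].to_numpy(), "g": sub.index.astype(str)})
    order = key.sort_values(["fdr", "p", "lfc", "g"]).index.to_numpy()
    genes = sub.index.to_numpy(dtype=object)[order]
    return list(genes[:n])


def _de_signature(disease_cells: CountMatrix, control_cells: CountMatrix,
                  engine: str, provenance: dict) -> DiseaseSignature:
    merged = concatenate(disease_cells, control_cells)
    normed = log_normalize(merged)
    idx_a = np.arange(disease_cells.n_cells)
    idx_b = np.arange(disease_cells.n_cells, merged.n_cells)
    res = de_between(normed, merged.gene_ids, idx_a, idx_b, engine=engine,
                     comparison=("disease", "control"))
    table = res.table.copy()
    table["pi"] = pi_score(table["lfc"].to_numpy(), table["fdr"].to_numpy())
    provenance = dict(provenance, engine=engine,
                      n_disease_cells=int(disease_cells.n_cells),
                      n_control_cells=int(control_cells.n_cells))
    return DiseaseSignature(table, provenance)


def build_dcs(disease_cells: CountMatrix, control_cells: CountMatrix,
              engine: str = "hurdle") -> DiseaseSignature:
    """DCS: disease-cluster cells vs pooled matched control-cluster cells.

    ``control_cells`` should already pool the cells of all selected control
    clusters; the contrast is a single two-group comparison.
    """
    return _de_signature(disease_cells, control_cells, engine,
                         {"kind": "dcs"})


def build_pseudobulk_signature(all_disease: CountMatrix,
                               all_control: CountMatrix,
                               engine: str = "hurdle") -> DiseaseSignature:
    """Pseudo-bulk signature: all disease-sample cells vs all control cells."""
    return _de_signature(all_disease, all_control, engine,
                         {"kind": "pseudobulk"})


# ------------------------------------------------------------------- ORA
def read_gmt(path: str | Path) -> dict[str, list]:
    """Read a GMT gene-set collection (name -> gene list)."""
    sets = _gseapy_read_gmt(str(path))
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def geneset_ora(ranked_sig: DiseaseSignature, genesets: dict[str, list],
                top_n: int = 200, alpha: float = 0.05,
                universe=None) -> pd.DataFrame:
    """Over-representation of the signature's top up-regulated genes in each
    gene set (one-sided Fisher), BH-corrected across sets.

    The universe defaults to the genes tested in the signature; gene sets
    are intersected with it.
    """
    if not genesets:
        raise ValueError("empty gene-set collection")
    top = ranked_sig.top_up_genes(n=top_n, alpha=alpha)
    uni = set(universe) if universe is not None else set(ranked_sig.table.index)
    rows = []
    for name in sorted(genesets):
        row = fisher_enrichment(top, genesets[name], uni)
        row.unit_label = name
        rows.append(row)
    return _enrichment_table(rows)
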