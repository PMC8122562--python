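"""Core data containers and plain-text I/O.

The pipeline operates on genes x cells UMI count matrices (10x-style MTX
triplets or dense TSV) and carries cluster assignments as cell -> label
mappings. Mitochondrial genes are recognised by the conventional ``MT-``
name prefix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

MITO_PREFIX = "MT-"


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifiers.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes in rows, cells in columns.
    gene_ids, cell_ids
        Unique identifiers matching the matrix dimensions.
    sample_label
        Free-text sample name, used to disambiguate cells when samples
        are concatenated.
    mito_mask
        Boolean per gene; derived from the ``MT-`` prefix when omitted.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    sample_label: str = ""
    mito_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts contain negative entries")
        if self.mito_mask is None:
            self.mito_mask = np.array(
                [str(g).upper().startswith(MITO_PREFIX) for g in self.gene_ids]
            )
        else:
            self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
            if self.mito_mask.shape != self.gene_ids.shape:
                raise ValueError("mito_mask length does not match gene_ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, cell_index: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the given cell positions."""
        return CountMatrix(
            self.counts[:, cell_index],
            self.gene_ids,
            self.cell_ids[cell_index],
            self.sample_label,
            self.mito_mask,
        )

    def subset_genes(self, gene_index: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[gene_index, :],
            self.gene_ids[gene_index],
            self.cell_ids,
            self.sample_label,
            self.mito_mask[gene_index],
        )

    def cells_by_id(self, ids) -> "CountMatrix":
        pos = pd.Index(self.cell_ids).get_indexer(list(ids))
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"unknown cell ids: {missing[:5]}")
        return self.subset_cells(pos)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_mtx_dir(cls, directory: str | Path, sample_label: str = "") -> "CountMatrix":
        """Read a 10x-style triplet: matrix.mtx(.gz), features.tsv(.gz) or
        genes.tsv(.gz), barcodes.tsv(.gz)."""
        directory = Path(directory)

        def find(*names):
            for n in names:
                for suff in ("", ".gz"):
                    p = directory / (n + suff)
                    if p.exists():
                        return p
            raise FileNotFoundError(f"none of {names} found in {directory}")

        mat_path = find("matrix.mtx")
        feat_path = find("features.tsv", "genes.tsv")
        bc_path = find("barcodes.tsv")
        with _open_maybe_gz(mat_path) as fh:
            counts = sp.csr_matrix(mmread(fh))
        with _open_maybe_gz(feat_path) as fh:
            feats = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        # prefer the gene-symbol column when present (10x: id, name, type)
        col = 1 if all(len(f) > 1 for f in feats) else 0
        genes = [f[col] for f in feats]
        if len(set(genes)) != len(genes):  # fall back to the id column
            genes = [f[0] for f in feats]
        with _open_maybe_gz(bc_path) as fh:
            barcodes = [line.strip() for line in fh if line.strip()]
        return cls(counts, np.array(genes, dtype=object),
                   np.array(barcodes, dtype=object),
                   sample_label or directory.name)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_label: str = "") -> "CountMatrix":
        """Dense genes x cells TSV with gene ids in the first column and
        cell ids in the header."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(sp.csr_matrix(df.to_numpy()),
                   df.index.to_numpy(dtype=object),
                   df.columns.to_numpy(dtype=object),
                   sample_label or Path(path).stem)

    @classmethod
    def load(cls, path: str | Path, sample_label: str = "") -> "CountMatrix":
        path = Path(path)
        if path.is_dir():
            return cls.from_mtx_dir(path, sample_label)
        return cls.from_tsv(path, sample_label)

    def to_mtx_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(self.counts))
        with open(directory / "features.tsv", "w") as fh:
            for g in self.gene_ids:
                fh.write(f"{g}\t{g}\tGene Expression\n")
        with open(directory / "barcodes.tsv", "w") as fh:
            for c in self.cell_ids:
                fh.write(f"{c}\n")


@dataclass
class ClusterAssignment:
    """Cell -> cluster labels (contiguous integers from 0, by decreasing
    cluster size)."""

    labels: pd.Series  # index: cell_id, values: int
    parameters: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)
        uniq = np.sort(self.labels.unique())
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster labels must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def cells_of(self, label: int) -> np.ndarray:
        return self.labels.index[self.labels == label].to_numpy(dtype=object)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"cell_id": self.labels.index, "cluster": self.labels.values})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClusterAssignment":
        df = pd.read_csv(path, sep="\t")
        return cls(pd.Series(df["cluster"].values, index=df["cell_id"].values))


def relabel_by_size(raw_labels: np.ndarray, cell_ids: np.ndarray,
                    parameters: Mapping | None = None) -> ClusterAssignment:
    """Map arbitrary community labels to 0..k-1 ordered by decreasing size
    (ties broken by the smallest member position, for determinism)."""
    raw = np.asarray(raw_labels)
    sizes = pd.Series(raw).value_counts()
    first_pos = {lab: int(np.argmax(raw == lab)) for lab in sizes.index}
    ranked = sorted(sizes.index, key=lambda l: (-sizes[l], first_pos[l]))
    order = {lab: i for i, lab in enumerate(ranked)}
    new = np.array([order[l] for l in raw])
    return ClusterAssignment(pd.Series(new, index=cell_ids),
                             dict(parameters or {}))
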