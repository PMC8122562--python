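"""Synthetic UMI counts and perturbation-signature libraries with planted truth.

Two generators make the whole protocol testable without external downloads:

* :func:`simulate_counts` draws negative-binomial (Gamma-Poisson) UMI counts
  for several healthy cell types plus, optionally, a rare "disease" population
  derived from one healthy type by up-regulating a marker panel and a disease
  gene program.  A configurable fraction of cells is generated to fail
  standard QC (low depth or high mitochondrial content).
* :func:`simulate_library` builds an L1000-style landmark-gene signature
  library in which the signatures of one planted mechanism-of-action (MOA)
  are anti-correlated with the disease program, emulating drugs that revert
  the disease state.

Truth labels are returned alongside (and can be written to a sidecar TSV);
the analysis pipeline never consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, MITO_PREFIX

DEFAULT_N_LANDMARK = 978


@dataclass
class SimScenario:
    """Parameters of the UMI-count simulation.

    Defaults emulate a droplet scRNA-seq sample of a few thousand cells in
    which the disease population is rare (~1% of cells) and over-expresses
    its marker panel and disease program by eight-fold, comfortably above
    the conventional two-fold differential-expression threshold.
    """

    n_cell_types: int = 8
    cells_per_type: Sequence[int] = (900, 800, 700, 600, 500, 450, 400, 350)
    n_genes: int = 3000
    n_marker_genes: int = 8
    disease_cluster_size: int = 55
    program_size: int = 100
    base_expression: np.ndarray | None = None  # per-gene mean, library-size scale
    dispersion: float = 5.0  # NB size theta; var = mu + mu^2/theta
    mito_fraction_healthy: float = 0.03
    qc_fail_fraction: float = 0.04
    seed: int = 0

    # secondary structure knobs
    n_mito_genes: int = 10
    type_de_genes: int = 120     # genes elevated per healthy cell type
    type_de_fold: float = 5.0
    disease_fold: float = 8.0    # fold-change on markers and program in disease cells
    mean_counts_per_cell: float = 2500.0
    program_overlaps_markers: bool = False

    def __post_init__(self) -> None:
        self.cells_per_type = tuple(int(c) for c in self.cells_per_type)
        if len(self.cells_per_type) != self.n_cell_types:
            raise ValueError("cells_per_type must have length n_cell_types")
        if any(c <= 0 for c in self.cells_per_type):
            raise ValueError("all cells_per_type must be positive")
        if self.disease_cluster_size < 0 or self.n_genes <= 0:
            raise ValueError("sizes must be non-negative")
        needed = self.n_mito_genes + self.n_marker_genes + self.program_size \
            + self.n_cell_types * self.type_de_genes
        if not self.program_overlaps_markers and needed > self.n_genes:
            raise ValueError(
                f"gene universe ({self.n_genes}) too small for the requested "
                f"structure ({needed} structured genes)")
        if self.n_marker_genes > self.n_genes:
            raise ValueError("marker count exceeds gene universe")


@dataclass
class TruthLabels:
    """Planted ground truth for one simulated sample."""

    cells: pd.DataFrame           # cell_id, cell_type, is_disease, qc_fail, qc_mode
    marker_genes: list
    program_genes: list
    type_de_gene_sets: dict
    disease_base_type: int
    program_lfc: pd.Series        # true log2 FC (disease vs base type), all genes

    def to_tsv(self, path: str | Path) -> None:
        self.cells.to_csv(path, sep="\t", index=False)


@dataclass
class _Profiles:
    """Per-cell-type expected expression, shared across samples of a scenario."""

    gene_ids: np.ndarray
    type_means: np.ndarray      # (n_types, n_genes), sums to mean_counts_per_cell
    disease_mean: np.ndarray
    marker_idx: np.ndarray
    program_idx: np.ndarray
    type_de_idx: dict


def _build_profiles(s: SimScenario) -> _Profiles:
    """Deterministic structural draw: gene universe, blocks, type profiles.

    Derived solely from ``s.seed`` so that disease and control samples of the
    same scenario share cell-type profiles.
    """
    rng = np.random.default_rng(s.seed)
    n = s.n_genes
    gene_ids = np.array(
        [f"{MITO_PREFIX}G{i + 1}" for i in range(s.n_mito_genes)]
        + [f"GENE{i + 1:05d}" for i in range(n - s.n_mito_genes)],
        dtype=object,
    )
    # disjoint structured blocks after the mito block
    cursor = s.n_mito_genes
    marker_idx = np.arange(cursor, cursor + s.n_marker_genes)
    cursor += s.n_marker_genes
    if s.program_overlaps_markers:
        program_idx = np.concatenate(
            [marker_idx[: min(s.n_marker_genes, s.program_size)],
             np.arange(cursor, cursor + max(0, s.program_size - s.n_marker_genes))])
        cursor += max(0, s.program_size - s.n_marker_genes)
    else:
        program_idx = np.arange(cursor, cursor + s.program_size)
        cursor += s.program_size
    type_de_idx = {}
    for t in range(s.n_cell_types):
        type_de_idx[t] = np.arange(cursor, cursor + s.type_de_genes)
        cursor += s.type_de_genes
    # readable names for the marker panel
    for j, i in enumerate(marker_idx):
        gene_ids[i] = f"MARKER{j + 1}"

    if s.base_expression is not None:
        base = np.asarray(s.base_expression, dtype=float).copy()
        if base.shape != (n,):
            raise ValueError("base_expression must have length n_genes")
    else:
        base = np.exp(rng.normal(0.0, 0.8, size=n))
    # markers are near-silent outside the disease population
    base[marker_idx] = np.quantile(base, 0.10)
    mito_idx = np.arange(s.n_mito_genes)

    def normalise(mu: np.ndarray) -> np.ndarray:
        """Fix the mito share and total library-size scale."""
        mu = mu.copy()
        non_mito = np.ones(n, dtype=bool)
        non_mito[mito_idx] = False
        mu[mito_idx] = 0.0
        mu[non_mito] *= (1.0 - s.mito_fraction_healthy) / mu[non_mito].sum()
        if s.mito_fraction_healthy > 0:
            w = rng.dirichlet(np.full(s.n_mito_genes, 5.0))
            mu[mito_idx] = s.mito_fraction_healthy * w
        return mu * s.mean_counts_per_cell

    type_means = np.empty((s.n_cell_types, n))
    for t in range(s.n_cell_types):
        mu = base.copy()
        mu[type_de_idx[t]] *= s.type_de_fold
        type_means[t] = normalise(mu)

    # disease population: base type 0 with markers + program boosted
    mu = base.copy()
    mu[type_de_idx[0]] *= s.type_de_fold
    mu[marker_idx] *= s.disease_fold
    mu[program_idx] *= s.disease_fold
    disease_mean = normalise(mu)

    return _Profiles(gene_ids, type_means, disease_mean,
                     marker_idx, program_idx, type_de_idx)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + mu^2/theta."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam)


def simulate_counts(scenario: SimScenario, *, disease: bool = True,
                    sample_label: str | None = None,
                    sampling_seed: int | None = None
                    ) -> tuple[CountMatrix, TruthLabels]:
    """Simulate one sample of UMI counts.

    Parameters
    ----------
    disease
        If True the sample carries the rare planted disease population in
        addition to the healthy cell types; if False only the healthy types
        are generated (a matched control sample).
    sampling_seed
        Seed for the count draws.  Defaults to ``scenario.seed``; cell-type
        profiles always derive from ``scenario.seed`` alone, so two samples
        of the same scenario share their expression programs.
    """
    s = scenario
    prof = _build_profiles(s)
    label = sample_label or ("disease" if disease else "control")
    seed = s.seed if sampling_seed is None else sampling_seed
    rng = np.random.default_rng([seed, 0x5CC] )

    groups: list[tuple[str, int, np.ndarray]] = []   # (type name, n, mean)
    for t in range(s.n_cell_types):
        groups.append((f"type{t}", s.cells_per_type[t], prof.type_means[t]))
    if disease and s.disease_cluster_size > 0:
        groups.append(("disease", s.disease_cluster_size, prof.disease_mean))

    mito_idx = np.arange(s.n_mito_genes)
    blocks, rows = [], []
    for name, n_cells, mean in groups:
        lib = np.clip(rng.lognormal(0.0, 0.25, size=n_cells), 0.6, 2.0)
        n_fail = int(round(s.qc_fail_fraction * n_cells))
        modes = np.array(["pass"] * n_cells, dtype=object)
        if n_fail:
            fail_cells = rng.choice(n_cells, size=n_fail, replace=False)
            half = n_fail // 2
            modes[fail_cells[:half]] = "low_depth"
            modes[fail_cells[half:]] = "high_mito"
        mu = mean[None, :] * lib[:, None]
        # planted QC failures: shallow libraries or inflated mito share
        low = modes == "low_depth"
        mu[low] *= 0.12
        high = modes == "high_mito"
        if high.any():
            mito_mass = mu[high][:, mito_idx].sum(axis=1)
            total = mu[high].sum(axis=1)
            target = 0.25
            boost = target * (total - mito_mass) / ((1 - target) * np.maximum(mito_mass, 1e-9))
            mu_h = mu[high]
            mu_h[:, mito_idx] *= boost[:, None]
            mu[high] = mu_h
        counts = _nb_sample(rng, mu, s.dispersion)
        blocks.append(sp.csr_matrix(counts.T))  # genes x cells
        for i in range(n_cells):
            rows.append((name, name == "disease", modes[i] != "pass", modes[i]))

    counts = sp.hstack(blocks, format="csr")
    cell_ids = np.array([f"{label}_C{i + 1:05d}" for i in range(counts.shape[1])],
                        dtype=object)
    cells = pd.DataFrame(rows, columns=["cell_type", "is_disease", "qc_fail", "qc_mode"])
    cells.insert(0, "cell_id", cell_ids)

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(prof.disease_mean / prof.type_means[0])
    truth = TruthLabels(
        cells=cells,
        marker_genes=list(prof.gene_ids[prof.marker_idx]),
        program_genes=list(prof.gene_ids[prof.program_idx]),
        type_de_gene_sets={t: list(prof.gene_ids[idx]) for t, idx in prof.type_de_idx.items()},
        disease_base_type=0,
        program_lfc=pd.Series(lfc, index=prof.gene_ids),
    )
    m = CountMatrix(counts, prof.gene_ids, cell_ids, sample_label=label)
    return m, truth


def simulate_sample_pair(scenario: SimScenario
                         ) -> tuple[CountMatrix, CountMatrix, TruthLabels]:
    """Disease sample plus matched control sample (shared profiles).

    The control sample contains the disease population's healthy base type,
    so downstream cluster matching has a true positive to find.
    """
    m_d, truth = simulate_counts(scenario, disease=True, sample_label="disease",
                                 sampling_seed=scenario.seed)
    m_c, truth_c = simulate_counts(scenario, disease=False, sample_label="control",
                                   sampling_seed=scenario.seed + 1)
    truth.cells = pd.concat([truth.cells, truth_c.cells], ignore_index=True)
    return m_d, m_c, truth


# --------------------------------------------------------------------------
# perturbation-signature library
# --------------------------------------------------------------------------

@dataclass
class LibScenario:
    """Parameters of the signature-library simulation.

    One MOA ("planted") receives signatures proportional to the negated,
    standardized disease program plus Gaussian noise, emulating perturbagens
    that revert the disease state; all other MOAs receive pure noise.
    """

    n_landmark_genes: int = DEFAULT_N_LANDMARK
    n_signatures: int = 1040
    n_moas: int = 51
    planted_moa_id: str = "MTOR inhibitor"
    planted_n_signatures: int = 20
    anti_correlation_strength: float = 0.8
    noise_sd: float = 1.0
    null_moa_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.anti_correlation_strength <= 1.0:
            raise ValueError("anti_correlation_strength must be in [0, 1]")
        if self.planted_n_signatures > self.n_signatures:
            raise ValueError("planted signatures exceed total signatures")
        if self.n_moas < 2:
            raise ValueError("need at least two MOA categories")


@dataclass
class SignatureLibrary:
    """Landmark genes x signatures matrix of moderated Z-scores + metadata."""

    landmark_genes: np.ndarray
    values: pd.DataFrame        # index: landmark genes, columns: signature ids
    metadata: pd.DataFrame      # signature_id, perturbagen_id, moa, cell_line, concentration

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.metadata["signature_id"]):
            raise ValueError("metadata rows must match value columns")
        if len(set(self.landmark_genes)) != len(self.landmark_genes):
            raise ValueError("landmark genes not unique")

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(directory / "library.tsv", sep="\t")
        self.metadata.to_csv(directory / "metadata.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, values_path: str | Path, metadata_path: str | Path
             ) -> "SignatureLibrary":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t")
        meta["moa"] = meta["moa"].where(meta["moa"].notna(), None)
        return cls(values.index.to_numpy(dtype=object), values, meta)


def landmark_panel(truth: TruthLabels, gene_ids: Sequence,
                   n: int = DEFAULT_N_LANDMARK, seed: int = 0) -> np.ndarray:
    """Choose a landmark-gene panel: the disease program plus random
    well-behaved genes from the universe (mitochondrial genes excluded)."""
    rng = np.random.default_rng([seed, 0x1A])
    program = [g for g in truth.program_genes]
    pool = [g for g in gene_ids
            if g not in set(program) and not str(g).upper().startswith(MITO_PREFIX)]
    n_extra = n - len(program)
    if n_extra < 0:
        raise ValueError("landmark panel smaller than the disease program")
    extra = rng.choice(np.array(pool, dtype=object), size=n_extra, replace=False)
    panel = np.concatenate([np.array(program, dtype=object), extra])
    return panel[np.argsort(panel.astype(str))]


def simulate_library(scenario: LibScenario, disease_program: pd.Series
                     ) -> tuple[SignatureLibrary, pd.DataFrame]:
    """Simulate a perturbation-signature library.

    Parameters
    ----------
    disease_program
        True gene-effect vector (e.g. planted log2 fold changes) indexed by
        the landmark genes; zero for landmarks outside the program.

    Returns
    -------
    library, truth
        The library and a per-signature truth table (signature_id, moa,
        is_planted).
    """
    s = scenario
    if len(disease_program) == 0:
        raise ValueError("disease_program is empty")
    if len(disease_program) != s.n_landmark_genes:
        raise ValueError(
            f"disease_program has {len(disease_program)} genes; scenario "
            f"declares {s.n_landmark_genes} landmarks")
    rng = np.random.default_rng([s.seed, 0x11B])
    genes = disease_program.index.to_numpy(dtype=object)
    prog = disease_program.to_numpy(dtype=float)
    sd = prog.std()
    z = (prog - prog.mean()) / (sd if sd > 0 else 1.0)

    n, k = s.n_landmark_genes, s.n_signatures
    moa_names = [s.planted_moa_id] + [f"MOA{i + 1:03d}" for i in range(s.n_moas - 1)]
    moas: list[str | None] = [s.planted_moa_id] * s.planted_n_signatures
    rest = k - s.planted_n_signatures
    n_null = int(round(s.null_moa_fraction * rest))
    for i in range(rest - n_null):
        moas.append(moa_names[1 + i % (s.n_moas - 1)])
    moas.extend([None] * n_null)

    values = rng.normal(0.0, s.noise_sd, size=(n, k))
    planted_cols = np.arange(s.planted_n_signatures)
    a = s.anti_correlation_strength
    if a == 1.0 and s.noise_sd == 0.0:
        values[:, planted_cols] = -z[:, None]
    else:
        # signal-to-noise set so that corr(sig, program) ~ -a
        signal_scale = a / np.sqrt(max(1.0 - a ** 2, 1e-12)) * s.noise_sd
        values[:, planted_cols] += -signal_scale * z[:, None]

    sig_ids = np.array([f"SIG{i + 1:05d}" for i in range(k)], dtype=object)
    meta = pd.DataFrame({
        "signature_id": sig_ids,
        "perturbagen_id": [f"CPD{i + 1:05d}" for i in range(k)],
        "moa": moas,
        "cell_line": [f"CL{1 + i % 5}" for i in range(k)],
        "concentration": np.round(10.0 ** rng.uniform(-2, 1, size=k), 4),
    })
    lib = SignatureLibrary(genes, pd.DataFrame(values, index=genes, columns=sig_ids),
                           meta)
    truth = pd.DataFrame({
        "signature_id": sig_ids,
        "moa": moas,
        "is_planted": [m == s.planted_moa_id for m in moas],
    })
    return lib, truth
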