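"""Zero-expression census of a gene set on a sparse single-cell count matrix.

Counts the cells with zero transcripts across every gene of a named set —
the adenylyl-cyclase census: mammalian cells carry ten adenylyl-cyclase
isoform genes (ADCY1..ADCY10 in human, Adcy1..Adcy10 in mouse), and a cell
with zero counts for all of them cannot be shown to express any isoform.
"Lacking expression" means count == 0, not a low-count threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ADCY_HUMAN",
    "ADCY_MOUSE",
    "CountMatrix",
    "CensusResult",
    "zero_expression_census",
    "simulate_count_matrix",
]

ADCY_HUMAN = tuple(f"ADCY{i}" for i in range(1, 11))
ADCY_MOUSE = tuple(f"Adcy{i}" for i in range(1, 11))


@dataclass
class CountMatrix:
    """Sparse gene x cell integer counts with gene symbols and barcodes."""

    genes: list[str]
    cells: list[str]
    counts: sparse.csr_matrix

    def __post_init__(self):
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.nnz and not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise ValueError("counts must be integers")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def write_mtx_dir(self, outdir: str | Path) -> Path:
        """Write the Cellranger triplet: matrix.mtx + genes.tsv + barcodes.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(outdir / "matrix.mtx", self.counts.astype(np.int64), field="integer")
        pd.DataFrame({"gene_id": self.genes, "gene_symbol": self.genes}).to_csv(
            outdir / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(self.cells).to_csv(outdir / "barcodes.tsv", header=False, index=False)
        return outdir

    @classmethod
    def read_mtx_dir(cls, mtx_dir: str | Path) -> "CountMatrix":
        mtx_dir = Path(mtx_dir)
        genes_path = mtx_dir / "genes.tsv"
        if not genes_path.exists():
            genes_path = mtx_dir / "features.tsv"
        genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, -1].tolist()
        barcodes = pd.read_csv(mtx_dir / "barcodes.tsv", header=None)[0].tolist()
        counts = sparse.csr_matrix(spio.mmread(mtx_dir / "matrix.mtx"))
        return cls(genes=genes, cells=barcodes, counts=counts)


@dataclass
class CensusResult:
    """Cells with zero counts across a whole gene set, plus per-gene breakdown."""

    n_zero: int
    n_total: int
    percent: float
    per_gene_positive: dict[str, int]
    genes_used: list[str]
    genes_missing: list[str]

    def __post_init__(self):
        if not 0 <= self.n_zero <= self.n_total:
            raise ValueError("inconsistent census counts")

    def to_json_dict(self) -> dict:
        return {
            "n_zero": self.n_zero,
            "n_total": self.n_total,
            "percent": self.percent,
            "per_gene_positive": self.per_gene_positive,
            "genes_used": self.genes_used,
            "genes_missing": self.genes_missing,
        }


def _percent_one_decimal(n_zero: int, n_total: int) -> float:
    """100*n_zero/n_total rounded half-up to one decimal (61.0-style output)."""
    frac = Decimal(100) * Decimal(n_zero) / Decimal(n_total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def zero_expression_census(
    matrix: CountMatrix,
    gene_set: list[str] | tuple[str, ...],
    match_mode: str = "strict",
    allow_missing: bool = False,
) -> CensusResult:
    """Count cells with zero counts across every gene of ``gene_set``.

    ``match_mode='strict'`` matches symbols exactly (and, without
    ``allow_missing``, requires every set gene in the matrix);
    ``'case_insensitive'`` bridges the human/mouse symbol dialects
    (ADCY1 vs Adcy1).  Missing genes, when allowed, are warned about and
    treated as all-zero.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene_set: a vacuous census is meaningless")
    if match_mode not in ("strict", "case_insensitive"):
        raise ValueError("match_mode must be 'strict' or 'case_insensitive'")

    if match_mode == "strict":
        lookup = {g: i for i, g in enumerate(matrix.genes)}
        keys = gene_set
    else:
        lookup = {g.lower(): i for i, g in enumerate(matrix.genes)}
        keys = [g.lower() for g in gene_set]

    rows, used, missing = [], [], []
    for g, key in zip(gene_set, keys):
        if key in lookup:
            rows.append(lookup[key])
            used.append(g)
        else:
            missing.append(g)
    if not rows:
        raise ValueError(f"none of the genes {gene_set} found in the matrix")
    if missing and not allow_missing:
        raise ValueError(
            f"genes missing from the matrix: {missing} (pass allow_missing=True "
            "to treat them as all-zero)"
        )
    if missing:
        warnings.warn(f"genes missing from the matrix, treated as all-zero: {missing}")

    sub = matrix.counts[rows]
    per_cell = np.asarray(sub.sum(axis=0)).ravel()
    n_zero = int((per_cell == 0).sum())
    per_gene = {
        g: int((sub[i].toarray() > 0).sum()) for i, g in enumerate(used)
    }
    per_gene.update({g: 0 for g in missing})
    return CensusResult(
        n_zero=n_zero,
        n_total=matrix.n_cells,
        percent=_percent_one_decimal(n_zero, matrix.n_cells),
        per_gene_positive=per_gene,
        genes_used=used,
        genes_missing=missing,
    )


def simulate_count_matrix(
    n_cells: int,
    gene_set: list[str] | tuple[str, ...] = ADCY_HUMAN,
    frac_zero: float = 0.61,
    n_background_genes: int = 50,
    seed: int = 0,
    set_gene_rate: float = 0.8,
    set_gene_dropout: float = 0.6,
    background_rate: float = 0.5,
) -> CountMatrix:
    """Synthetic count matrix with a controlled all-zero fraction on a gene set.

    Exactly ``round(n_cells * frac_zero)`` cells (half-up) get zero counts on
    every set gene; every other cell gets at least one count on at least one
    set gene.  Set-gene counts follow a zero-inflated Poisson
    (dropout ``set_gene_dropout``, rate ``set_gene_rate``); background genes
    are plain Poisson noise.
    """
    if not 0.0 <= frac_zero <= 1.0:
        raise ValueError("frac_zero must be in [0,1]")
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    rng = np.random.default_rng(seed)
    gene_set = list(gene_set)
    n_zero = int(np.floor(n_cells * frac_zero + 0.5))
    zero_cells = rng.permutation(n_cells)[:n_zero]
    is_zero = np.zeros(n_cells, dtype=bool)
    is_zero[zero_cells] = True

    counts = np.zeros((len(gene_set), n_cells), dtype=np.int64)
    expressed = ~is_zero
    n_expr = int(expressed.sum())
    if n_expr:
        draws = rng.poisson(set_gene_rate, size=(len(gene_set), n_expr))
        dropout = rng.random((len(gene_set), n_expr)) < set_gene_dropout
        draws[dropout] = 0
        # guarantee detectability: cells outside the zero group must show >= 1 count
        allzero = draws.sum(axis=0) == 0
        if allzero.any():
            which_gene = rng.integers(0, len(gene_set), size=int(allzero.sum()))
            draws[which_gene, np.flatnonzero(allzero)] = 1
        counts[:, expressed] = draws

    background = rng.poisson(background_rate, size=(n_background_genes, n_cells))
    genes = gene_set + [f"GENE{i:04d}" for i in range(n_background_genes)]
    full = sparse.csr_matrix(np.vstack([counts, background]))
    barcodes = [f"CELL{i:06d}" for i in range(n_cells)]
    return CountMatrix(genes=genes, cells=barcodes, counts=full)
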