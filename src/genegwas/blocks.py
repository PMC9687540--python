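"""Gene blocks: SNP-to-gene assignment, filters, and per-gene regression designs.

A gene block is the set of SNPs whose position falls inside a gene's span
(1-based inclusive, strand ignored). Each block is turned into a regression
design by one of three integration rules:

EPC
    the leading principal components of the centered within-gene dosage
    matrix, the smallest set whose cumulative explained variance reaches a
    threshold (default 80%);
FPC
    the first principal component only;
ALLSNP
    the centered dosage columns themselves, reduced to a maximal linearly
    independent subset.

PCA is computed on centered but unscaled dosages by default
(variance-weighted components); ``scale=True`` standardises each SNP to
unit variance first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import DegenerateGeneError
from .panel import GeneCatalog, GenotypePanel

logger = logging.getLogger(__name__)

#: Relative tolerance for the rank-revealing QR used by ALLSNP designs.
RANK_TOL = 1e-8


@dataclass
class GeneBlock:
    """A gene's genomic span and the panel indices of its member SNPs."""

    gene_id: str
    chrom: str
    start: int
    end: int
    snp_indices: np.ndarray

    def __post_init__(self) -> None:
        self.snp_indices = np.asarray(self.snp_indices, dtype=np.int64)

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


@dataclass
class GeneDesign:
    """Regression design for one gene.

    ``columns`` is an n x k matrix of centered regressors, ``df_beta`` = k,
    and ``explained_variance`` the cumulative variance fraction captured by
    the retained PCs (1.0 for ALLSNP).
    """

    gene_id: str
    columns: np.ndarray
    df_beta: int
    method: str
    explained_variance: float = field(default=1.0)


def filter_by_maf(panel: GenotypePanel, threshold: float) -> GenotypePanel:
    """Retain SNPs with minor-allele frequency >= threshold; order preserved."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must lie in [0, 0.5], got {threshold}")
    if threshold == 0.0:
        return panel
    f = panel.allele_freq
    keep = np.minimum(f, 1.0 - f) >= threshold
    out = panel.take_snps(keep)
    if out.n_snps == 0:
        logger.warning("MAF filter at %.3g removed every SNP", threshold)
    return out


def assign_snps_to_genes(panel: GenotypePanel, catalog: GeneCatalog) -> list[GeneBlock]:
    """Assign each SNP to every gene whose span contains it.

    Boundaries are inclusive; a SNP inside two overlapping genes appears in
    both blocks. Genes with zero SNPs are omitted. The panel must be sorted
    by (chrom, pos); per-chromosome assignment is a binary search on the
    sorted coordinate array.
    """
    # group panel SNPs by chromosome
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(panel.chrom.astype(str)):
        mask = panel.chrom.astype(str) == c
        idx = np.nonzero(mask)[0]
        pos = panel.pos[idx]
        if np.any(np.diff(pos) < 0):
            raise ValueError("panel positions must be sorted within chromosome; "
                             "call panel.sort_canonical() first")
        by_chrom[c] = (pos, idx)

    cat_chroms = set(map(str, catalog.chrom))
    unmatched = sorted(cat_chroms - set(by_chrom))
    if unmatched:
        logger.warning("catalog chromosome(s) absent from panel: %s",
                       ", ".join(unmatched))
    orphan = sorted(set(by_chrom) - cat_chroms)
    if orphan:
        logger.warning("panel chromosome(s) absent from catalog: %s",
                       ", ".join(orphan))

    blocks: list[GeneBlock] = []
    for i in range(len(catalog)):
        c = str(catalog.chrom[i])
        if c not in by_chrom:
            continue
        pos, idx = by_chrom[c]
        lo = np.searchsorted(pos, catalog.start[i], side="left")
        hi = np.searchsorted(pos, catalog.end[i], side="right")
        if hi > lo:
            blocks.append(GeneBlock(
                gene_id=str(catalog.gene_id[i]),
                chrom=c,
                start=int(catalog.start[i]),
                end=int(catalog.end[i]),
                snp_indices=idx[lo:hi],
            ))
    return blocks


def filter_genes_by_snp_count(blocks: list[GeneBlock], min_snps: int) -> list[GeneBlock]:
    """Keep blocks with at least ``min_snps`` member SNPs."""
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    return [b for b in blocks if b.n_snps >= min_snps]


def _centered_columns(block: GeneBlock, panel: GenotypePanel,
                      scale: bool) -> np.ndarray:
    X = panel.imputed()[:, block.snp_indices]
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise DegenerateGeneError(
            f"gene {block.gene_id}: all {block.n_snps} SNP columns are "
            "monomorphic within the sample"
        )
    X = X[:, keep]
    if scale:
        X = X / sd[keep]
    return X


def build_gene_design(block: GeneBlock, panel: GenotypePanel,
                      method: str = "EPC", epc_threshold: float = 0.80,
                      scale: bool = False) -> GeneDesign:
    """Build the regression design for one gene under EPC/FPC/ALLSNP.

    Missing dosages are imputed to the column mean; columns are
    mean-centered; monomorphic-within-sample columns are dropped. PCA is
    the SVD of the centered (optionally scaled) matrix; components are
    ordered by decreasing singular value.
    """
    method = method.upper()
    if method not in {"EPC", "FPC", "ALLSNP"}:
        raise ValueError(f"unknown design method {method!r}")
    X = _centered_columns(block, panel, scale)

    if method == "ALLSNP":
        # reduce to a maximal linearly independent column subset
        _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        rank = int(np.sum(diag > RANK_TOL * diag[0]))
        cols = np.sort(piv[:rank])  # keep original SNP order
        return GeneDesign(
            gene_id=block.gene_id,
            columns=X[:, cols],
            df_beta=rank,
            method="ALLSNP",
            explained_variance=1.0,
        )

    U, sv, _ = np.linalg.svd(X, full_matrices=False)
    var = sv ** 2
    total = var.sum()
    frac = np.cumsum(var) / total
    if method == "FPC":
        k = 1
    else:
        if not 0.0 < epc_threshold <= 1.0:
            raise ValueError("epc_threshold must lie in (0, 1]")
        k = int(np.searchsorted(frac, epc_threshold - 1e-12) + 1)
        k = min(k, len(sv))
    scores = U[:, :k] * sv[:k]
    return GeneDesign(
        gene_id=block.gene_id,
        columns=scores,
        df_beta=k,
        method=method,
        explained_variance=float(frac[k - 1]),
    )


def design_summary(blocks: list[GeneBlock], panel: GenotypePanel,
                   method: str = "EPC", epc_threshold: float = 0.80,
                   scale: bool = False):
    """Per-gene design summary (gene_id, n_snps, df_beta, explained_variance).

    Feeds the SNP-count / PC-count histogram report. Degenerate genes are
    skipped with a log entry.
    """
    import pandas as pd

    rows = []
    for b in blocks:
        try:
            d = build_gene_design(b, panel, method, epc_threshold, scale)
        except DegenerateGeneError as exc:
            logger.info("skipping degenerate gene: %s", exc)
            continue
        rows.append((b.gene_id, b.n_snps, d.df_beta, d.explained_variance))
    return pd.DataFrame(rows, columns=["gene_id", "n_snps", "df_beta",
                                       "explained_variance"])
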