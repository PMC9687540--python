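"""Core in-memory containers: genotype panel, gene catalog, phenotype vector.

The dosage matrix is sample-major (n individuals x m SNPs) and holds
reference->alternate allele counts in {0, 1, 2}; missing genotypes are NaN.
Inbred-line panels carry only {0, 2}. Alternate-allele frequency is defined
as mean(dosage)/2 over non-missing entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import GeneGwasError

logger = logging.getLogger(__name__)


def allele_frequencies(dosage: np.ndarray) -> np.ndarray:
    """Per-SNP alternate-allele frequency, mean(dosage)/2 over non-missing.

    All-missing columns get NaN.
    """
    ok = ~np.isnan(dosage)
    counts = ok.sum(axis=0).astype(float)
    sums = np.where(ok, dosage, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / (2.0 * counts), np.nan)


@dataclass
class GenotypePanel:
    """Sample-major dosage matrix with per-SNP metadata.

    Attributes
    ----------
    sample_ids : (n,) array of str
    snp_ids : (m,) array of str
    chrom : (m,) array of str
        Chromosome label per SNP.
    pos : (m,) array of int
        1-based coordinate per SNP.
    dosage : (n, m) float array
        Alternate-allele counts in [0, 2]; NaN marks missing genotypes.
    allele_freq : (m,) float array
        Alternate-allele frequency in [0, 1], mean(dosage)/2 over
        non-missing entries.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    allele_freq: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        if self.dosage.ndim != 2:
            raise GeneGwasError("dosage must be a 2-D (samples x SNPs) matrix")
        n, m = self.dosage.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise GeneGwasError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if self.allele_freq is None:
            self.allele_freq = allele_frequencies(self.dosage)
        else:
            self.allele_freq = np.asarray(self.allele_freq, dtype=np.float64)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def imputed(self) -> np.ndarray:
        """Dosage copy with missing entries filled by the per-SNP mean."""
        X = self.dosage.copy()
        if np.isnan(X).any():
            col_mean = 2.0 * self.allele_freq
            nan_r, nan_c = np.nonzero(np.isnan(X))
            X[nan_r, nan_c] = col_mean[nan_c]
        return X

    def take_snps(self, index: np.ndarray) -> "GenotypePanel":
        """Sub-panel restricted to SNPs selected by a boolean mask or index."""
        index = np.asarray(index)
        return GenotypePanel(
            sample_ids=self.sample_ids,
            snp_ids=self.snp_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            dosage=self.dosage[:, index],
            allele_freq=self.allele_freq[index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypePanel":
        """Sub-panel restricted to selected samples; allele_freq recomputed."""
        index = np.asarray(index)
        return GenotypePanel(
            sample_ids=self.sample_ids[index],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            dosage=self.dosage[index, :],
        )

    def sort_canonical(self) -> "GenotypePanel":
        """Sort SNPs by (chrom, pos); stable, so input order breaks ties."""
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return self.take_snps(order)


@dataclass
class GeneCatalog:
    """Gene records: unique IDs with 1-based inclusive genomic spans."""

    gene_id: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray

    def __post_init__(self) -> None:
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype=object)
        ids, counts = np.unique(self.gene_id.astype(str), return_counts=True)
        dup = ids[counts > 1]
        if dup.size:
            raise GeneGwasError(f"duplicate gene_id(s): {', '.join(dup)}")
        if np.any(self.start > self.end):
            bad = self.gene_id[self.start > self.end]
            raise GeneGwasError(f"start > end for gene(s): {', '.join(map(str, bad))}")

    def __len__(self) -> int:
        return len(self.gene_id)


@dataclass
class PhenotypeVector:
    """Trait measurements keyed by sample ID."""

    sample_ids: np.ndarray
    values: np.ndarray
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.sample_ids) != len(self.values):
            raise GeneGwasError("sample_ids and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise GeneGwasError("phenotype values must be finite")

    def __len__(self) -> int:
        return len(self.values)
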