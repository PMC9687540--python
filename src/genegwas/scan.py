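"""Whole-genome gene scanning.

The two-round strategy: one fast pass with every gene's polygenic
heritability fixed at the trait's genomic estimate (the EMMAX shortcut, a
single whitening reused genome-wide), then a second pass that re-optimizes
h2 only for genes passing the screening significance level, searching
downward from the genomic estimate. Thresholding uses the Bonferroni
correction over tested genes; calibration is summarized by the
median-based genomic-control lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import (GeneBlock, assign_snps_to_genes, build_gene_design,
                     filter_by_maf, filter_genes_by_snp_count)
from .errors import DegenerateGeneError, GeneGwasError
from .kinship import SpectralKinship, compute_rrm, identity_spectral, spectral_decompose
from .lmm import (_ProfileObjective, barebones_fit, estimate_genomic_h2,
                  optimize_h2, weights)
from .panel import GeneCatalog, GenotypePanel, PhenotypeVector

logger = logging.getLogger(__name__)

#: Median of the 1-df chi-square distribution.
CHI2_1_MEDIAN = 0.4549364231195724

DESIGN_METHODS = {"EPC", "FPC", "ALLSNP"}


@dataclass
class ScanConfig:
    """Tunable knobs of the gene scan."""

    maf_min: float = 0.05
    min_snps: int = 10
    epc_threshold: float = 0.80
    pca_scale: bool = False
    screen_alpha: float = 0.05
    alpha: float = 0.05
    mode: str = "tworound"          # emmax | tworound | full
    kinship_method: str = "vanraden"
    h2_full_range: bool = False     # lift the genomic-h2 search-down bound


@dataclass
class GeneScanRecord:
    """Per-gene fit result."""

    gene_id: str
    chrom: str
    start: int
    end: int
    n_snps: int
    df_beta: int
    h2_used: float
    beta_norm: float
    sigma2e: float
    F: float
    p: float
    neg_log10_p: float
    neg2logL: float
    method: str
    mode: str


@dataclass
class ScanResult:
    """Scan output: records plus trait-level summaries."""

    records: list[GeneScanRecord]
    genomic_h2: float
    n_genes_tested: int
    bonferroni_neg_log10: float
    gc_lambda: float
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def pvalues(self) -> np.ndarray:
        return np.array([r.p for r in self.records])


def _design_method(method: str) -> str:
    """Map a scan method to its gene-design rule (EPCLM uses EPC designs)."""
    m = method.upper()
    if m == "EPCLM":
        return "EPC"
    if m not in DESIGN_METHODS:
        raise ValueError(f"unknown scan method {method!r}")
    return m


def _record_from_fit(block: GeneBlock, design, fit, method: str,
                     mode: str) -> GeneScanRecord:
    beta_gene = fit.beta[1:]
    p = fit.p
    return GeneScanRecord(
        gene_id=block.gene_id, chrom=block.chrom, start=block.start,
        end=block.end, n_snps=block.n_snps, df_beta=fit.df_beta,
        h2_used=fit.h2, beta_norm=float(np.linalg.norm(beta_gene)),
        sigma2e=fit.sigma2e, F=fit.F, p=p,
        neg_log10_p=float(-np.log10(p)), neg2logL=fit.neg2logL,
        method=method.upper(), mode=mode,
    )


def emmax_scan(panel: GenotypePanel, blocks: list[GeneBlock], y: np.ndarray,
               spectral: SpectralKinship, method: str = "EPC",
               h2_fixed: float = 0.0, epc_threshold: float = 0.80,
               pca_scale: bool = False
               ) -> tuple[list[GeneScanRecord], list[tuple[str, str]]]:
    """Single-pass scan with h2 fixed for every gene (one whitening).

    Returns (records, skipped); degenerate genes are skipped with a reason,
    never fatal.
    """
    y = np.asarray(y, dtype=np.float64)
    dmethod = _design_method(method)
    wdiag = weights(spectral.S, h2_fixed)
    sw = np.sqrt(wdiag)
    Ut = spectral.U.T
    yt = (Ut @ y) / sw
    one_t = (Ut @ np.ones(len(y))) / sw

    records: list[GeneScanRecord] = []
    skipped: list[tuple[str, str]] = []
    for block in blocks:
        try:
            design = build_gene_design(block, panel, dmethod, epc_threshold,
                                       pca_scale)
            xt = (Ut @ design.columns) / sw[:, None]
            xstar = np.hstack([one_t[:, None], xt])
            fit = barebones_fit(yt, xstar, wdiag, h2_fixed)
        except (DegenerateGeneError, GeneGwasError) as exc:
            logger.info("skipping gene %s: %s", block.gene_id, exc)
            skipped.append((block.gene_id, str(exc)))
            continue
        records.append(_record_from_fit(block, design, fit, method, "emmax"))
    return records, skipped


def refine_scan(records: list[GeneScanRecord], screen_alpha: float,
                y: np.ndarray, spectral: SpectralKinship,
                panel: GenotypePanel, blocks: list[GeneBlock],
                h2_upper: float | None = None, epc_threshold: float = 0.80,
                pca_scale: bool = False) -> list[GeneScanRecord]:
    """Re-fit screened genes (emmax p <= screen_alpha) with optimized h2.

    The per-gene search is bounded above by ``h2_upper`` (the genomic
    heritability estimate — the search-down strategy); unscreened records
    pass through untouched.
    """
    if not 0.0 < screen_alpha <= 1.0:
        raise ValueError("screen_alpha must lie in (0, 1]")
    y = np.asarray(y, dtype=np.float64)
    by_id = {b.gene_id: b for b in blocks}
    out: list[GeneScanRecord] = []
    for rec in records:
        if rec.p > screen_alpha or rec.mode == "refined":
            out.append(rec)
            continue
        block = by_id[rec.gene_id]
        design = build_gene_design(block, panel, _design_method(rec.method),
                                   epc_threshold, pca_scale)
        h2hat = optimize_h2(y, design.columns, spectral, upper_bound=h2_upper)
        obj = _ProfileObjective(y, design.columns, spectral)
        fit = obj.fit(h2hat)
        out.append(_record_from_fit(block, design, fit, rec.method, "refined"))
    return out


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """-log10(alpha / n_genes), the gene-significance cutoff."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(-np.log10(alpha / n_genes))


def genomic_control_lambda(pvalues: np.ndarray) -> float:
    """Median-based inflation factor of 1-df chi-square quantiles.

    Each p is mapped to q = Q_{chi2,1}(1 - p); lambda is median(q) divided
    by the 1-df chi-square median 0.4549. Lambda near 1 indicates
    calibrated tests; > 1 inflation, < 1 deflation.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q = stats.chi2.isf(p, df=1)
    return float(np.median(q) / CHI2_1_MEDIAN)


def qq_points(pvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10(p) pairs for a Q-Q plot.

    Observed values are sorted descending; expected quantiles use the
    (i - 0.5)/N plotting positions.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value array")
    N = p.size
    observed = -np.log10(np.sort(p))  # ascending p -> descending -log10
    expected = -np.log10((np.arange(1, N + 1) - 0.5) / N)
    return expected, observed


def snp_retention_percent(n_kept: int, n_total: int) -> float:
    """Percentage of SNPs retained by a filter step."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_kept / n_total


def format_filter_summary(n_kept: int, n_total: int,
                          label: str = "SNPs") -> str:
    """Human-readable filter bookkeeping line, percentage at 2 d.p."""
    pct = snp_retention_percent(n_kept, n_total)
    return f"{n_kept:,} of {n_total:,} {label} retained ({pct:.2f}%)"


def shared_qtg_table(results_by_trait: dict[str, ScanResult],
                     threshold: float) -> pd.DataFrame:
    """Genes significant (neg_log10_p >= threshold) in at least two traits.

    Rows are sorted by descending trait count, then gene_id; trait lists
    are sorted, so the table is invariant to input trait order.
    """
    if len(results_by_trait) < 2:
        raise GeneGwasError("shared-QTG table needs >= 2 traits")
    hits: dict[str, list[str]] = {}
    for trait in sorted(results_by_trait):
        for rec in results_by_trait[trait].records:
            if rec.neg_log10_p >= threshold:
                hits.setdefault(rec.gene_id, []).append(trait)
    rows = [
        (gid, len(traits), ",".join(sorted(traits)))
        for gid, traits in hits.items() if len(traits) >= 2
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["gene_id", "n_traits", "traits"])


def _join_samples(panel: GenotypePanel, phenotype: PhenotypeVector
                  ) -> tuple[GenotypePanel, np.ndarray]:
    """Inner-join panel and phenotype on sample ID (panel order kept)."""
    pheno_map = {str(s): v for s, v in zip(phenotype.sample_ids,
                                           phenotype.values)}
    keep = np.array([str(s) in pheno_map for s in panel.sample_ids])
    if keep.sum() < 2:
        raise GeneGwasError(
            f"only {int(keep.sum())} sample(s) shared between genotypes and "
            "phenotype; need at least 2"
        )
    sub = panel.take_samples(np.nonzero(keep)[0])
    y = np.array([pheno_map[str(s)] for s in sub.sample_ids])
    return sub, y


def run_gene_gwas(panel: GenotypePanel, catalog: GeneCatalog,
                  phenotype: PhenotypeVector, method: str = "EPC",
                  config: ScanConfig | None = None) -> ScanResult:
    """Full pipeline: filters -> blocks -> kinship -> genomic h2 -> scan.

    ``method`` is one of EPC, FPC, ALLSNP (mixed model) or EPCLM (the same
    EPC design fitted by ordinary least squares, no polygenic term — the
    inflated baseline). Deterministic given inputs and config.
    """
    cfg = config or ScanConfig()
    method_u = method.upper()
    panel, y = _join_samples(panel, phenotype)

    n_before = panel.n_snps
    panel = filter_by_maf(panel, cfg.maf_min)
    logger.info(format_filter_summary(panel.n_snps, n_before,
                                      f"SNPs (MAF >= {cfg.maf_min})"))
    panel = panel.sort_canonical()

    blocks = assign_snps_to_genes(panel, catalog)
    n_assigned = len(blocks)
    blocks = filter_genes_by_snp_count(blocks, cfg.min_snps)
    logger.info("genes with SNPs: %d; genes with >= %d SNPs: %d",
                n_assigned, cfg.min_snps, len(blocks))
    if not blocks:
        raise GeneGwasError("no genes survive the SNP-count filter")
    covered = len(set(np.concatenate([b.snp_indices for b in blocks])))
    logger.info(format_filter_summary(covered, panel.n_snps,
                                      "SNPs covered by tested genes"))

    if method_u == "EPCLM":
        spectral = identity_spectral(panel.n_samples)
        genomic_h2 = 0.0
    else:
        K = compute_rrm(panel, cfg.kinship_method)
        spectral = spectral_decompose(K)
        genomic_h2 = estimate_genomic_h2(y, spectral)
    logger.info("genomic heritability estimate: %.4f", genomic_h2)

    records, skipped = emmax_scan(panel, blocks, y, spectral, method_u,
                                  h2_fixed=genomic_h2,
                                  epc_threshold=cfg.epc_threshold,
                                  pca_scale=cfg.pca_scale)
    if not records:
        raise GeneGwasError("no genes could be tested")

    if method_u != "EPCLM" and cfg.mode in ("tworound", "full"):
        screen = 1.0 if cfg.mode == "full" else cfg.screen_alpha
        h2_upper = None if cfg.h2_full_range else max(genomic_h2, 1e-6)
        records = refine_scan(records, screen, y, spectral, panel, blocks,
                              h2_upper=h2_upper,
                              epc_threshold=cfg.epc_threshold,
                              pca_scale=cfg.pca_scale)
    elif cfg.mode not in ("emmax", "tworound", "full"):
        raise ValueError(f"unknown scan mode {cfg.mode!r}")

    pvals = np.array([r.p for r in records])
    return ScanResult(
        records=records,
        genomic_h2=genomic_h2,
        n_genes_tested=len(records),
        bonferroni_neg_log10=bonferroni_threshold(len(records), cfg.alpha),
        gc_lambda=genomic_control_lambda(pvals),
        skipped=skipped,
    )

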