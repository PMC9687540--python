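"""Synthetic inbred-line panels, QTN architectures, phenotypes and power studies.

The generator emulates the features of a maize inbred diversity panel that
matter to a gene-based scan: dosages in {0, 2}, genes of >= 10 SNPs with
within-gene linkage disequilibrium, minor-allele frequencies above 5%, and
causal variants (QTNs) clustered in a fixed set of causal genes with
gamma-distributed effect magnitudes scaled to a target fraction of
phenotypic variance (60% by default).

Within-gene LD comes from a latent Gaussian AR(1) process along the
gene's SNPs, thresholded at each SNP's frequency quantile; optional
population structure adds Balding-Nichols subpopulation frequency shifts.

The power study fixes the genotype panel and the causal-gene set across
replicates and redraws QTN placement, effect sizes and residuals each
replicate; power is the fraction of causal genes declared significant,
type-I error the fraction of non-causal genes passing the same threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import GeneBlock, assign_snps_to_genes, build_gene_design, filter_by_maf, filter_genes_by_snp_count
from .errors import GeneGwasError
from .kinship import SpectralKinship, compute_rrm, identity_spectral, spectral_decompose
from .lmm import _ProfileObjective, estimate_genomic_h2, optimize_h2
from .panel import GeneCatalog, GenotypePanel, PhenotypeVector
from .scan import GeneScanRecord, ScanResult, bonferroni_threshold, emmax_scan, genomic_control_lambda, refine_scan

logger = logging.getLogger(__name__)

#: Base-pair spacing of simulated SNPs and gap between simulated genes.
SNP_SPACING = 100
GENE_GAP = 10_000
N_SIM_CHROMS = 10


@dataclass
class SimConfig:
    """Study conditions of the simulation harness.

    Defaults are the scaled-down design used throughout the test suite;
    the full-scale validation design (n=2000+, thousands of genes,
    50 replicates) uses the same machinery with larger counts.
    """

    n_individuals: int = 500
    n_genes: int = 200
    snps_per_gene: tuple[int, int] = (10, 20)
    within_gene_ld_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    inbred: bool = True
    n_causal_genes: int = 20
    n_qtns: int = 100
    h2_target: float = 0.6
    effect_gamma_shape: float = 1.66
    effect_gamma_scale: float = 0.4
    effects_positive: bool = False
    n_reps: int = 10
    seed: int = 0
    n_subpops: int = 0          # 0 -> no population structure
    fst: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2_target < 1.0:
            raise ValueError("h2_target must lie in (0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError(f"infeasible maf_range {self.maf_range}")
        if min(self.n_individuals, self.n_genes, self.n_qtns,
               self.n_causal_genes, self.n_reps) < 1:
            raise ValueError("all counts must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("snps_per_gene", "maf_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        import yaml

        d = asdict(self)
        d["snps_per_gene"] = list(d["snps_per_gene"])
        d["maf_range"] = list(d["maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated architecture."""

    causal_gene_ids: list[str]
    qtn_indices: np.ndarray      # panel SNP indices of the QTNs
    qtn_snp_ids: np.ndarray
    effects: np.ndarray          # signed effect sizes, aligned with qtn_indices
    realized_h2: float | None = None


def _ar1_latent(rng: np.random.Generator, n: int, m: int,
                rho: float) -> np.ndarray:
    """n x m latent Gaussian with AR(1) correlation rho along columns."""
    Z = np.empty((n, m))
    Z[:, 0] = rng.standard_normal(n)
    if m > 1:
        innov = rng.standard_normal((n, m - 1)) * np.sqrt(1.0 - rho ** 2)
        for j in range(1, m):
            Z[:, j] = rho * Z[:, j - 1] + innov[:, j - 1]
    return Z


def _subpop_freqs(rng: np.random.Generator, f: np.ndarray, n_subpops: int,
                  fst: float) -> np.ndarray:
    """Balding-Nichols subpopulation allele frequencies, (n_subpops, m)."""
    if n_subpops <= 1 or fst <= 0:
        return np.tile(f, (max(n_subpops, 1), 1))
    a = f * (1.0 - fst) / fst
    b = (1.0 - f) * (1.0 - fst) / fst
    out = rng.beta(a, b, size=(n_subpops, len(f)))
    return np.clip(out, 1e-4, 1.0 - 1e-4)


def simulate_genotype_panel(config: SimConfig, seed: int | None = None
                            ) -> tuple[GenotypePanel, GeneCatalog]:
    """Simulate an LD-structured dosage panel and its gene catalog.

    Genes are tiled on synthetic chromosomes with non-overlapping spans;
    SNP count per gene is uniform over ``snps_per_gene`` and target
    alternate-allele frequencies uniform over ``maf_range``. Identical
    (config, seed) pairs give identical panels.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_individuals
    rho = config.within_gene_ld_rho
    if not 0.0 <= rho < 1.0:
        raise ValueError("within_gene_ld_rho must lie in [0, 1)")

    if config.n_subpops > 1:
        subpop = np.repeat(np.arange(config.n_subpops),
                           int(np.ceil(n / config.n_subpops)))[:n]
    else:
        subpop = np.zeros(n, dtype=int)

    genes_per_chrom = int(np.ceil(config.n_genes / N_SIM_CHROMS))
    snp_ids, chroms, poss = [], [], []
    g_ids, g_chrom, g_start, g_end = [], [], [], []
    dosage_cols = []
    next_start = {c: 1 for c in range(1, N_SIM_CHROMS + 1)}

    for g in range(config.n_genes):
        chrom = g // genes_per_chrom + 1
        m = int(rng.integers(config.snps_per_gene[0],
                             config.snps_per_gene[1] + 1))
        f = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
        fsub = _subpop_freqs(rng, f, config.n_subpops, config.fst)
        thresh = stats.norm.ppf(fsub)          # (n_subpops, m)
        t_ind = thresh[subpop, :]              # (n, m) per-individual cutoffs

        if config.inbred:
            Z = _ar1_latent(rng, n, m, rho)
            D = 2.0 * (Z < t_ind)
        else:
            h1 = (_ar1_latent(rng, n, m, rho) < t_ind).astype(float)
            h2 = (_ar1_latent(rng, n, m, rho) < t_ind).astype(float)
            D = h1 + h2
        dosage_cols.append(D)

        start = next_start[chrom]
        pos = start + SNP_SPACING * np.arange(m)
        end = int(pos[-1])
        next_start[chrom] = end + GENE_GAP
        gid = f"gene{g + 1:05d}"
        g_ids.append(gid)
        g_chrom.append(str(chrom))
        g_start.append(start)
        g_end.append(end)
        snp_ids.extend(f"{gid}_snp{j + 1}" for j in range(m))
        chroms.extend([str(chrom)] * m)
        poss.extend(int(p) for p in pos)

    panel = GenotypePanel(
        sample_ids=np.array([f"ind{i + 1:05d}" for i in range(n)],
                            dtype=object),
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        dosage=np.hstack(dosage_cols),
    )
    catalog = GeneCatalog(
        gene_id=np.array(g_ids, dtype=object),
        chrom=np.array(g_chrom, dtype=object),
        start=np.array(g_start, dtype=np.int64),
        end=np.array(g_end, dtype=np.int64),
        strand=np.array(["+"] * len(g_ids), dtype=object),
    )
    return panel.sort_canonical(), catalog


def draw_qtn_architecture(blocks: list[GeneBlock], n_causal_genes: int,
                          n_qtns: int, seed: int | None = None, *,
                          rng: np.random.Generator | None = None,
                          causal_gene_ids: list[str] | None = None,
                          shape: float = 1.66, scale: float = 0.4,
                          effects_positive: bool = False) -> SimulationTruth:
    """Place QTNs in randomly chosen causal genes with gamma effects.

    Causal genes are sampled without replacement (or fixed via
    ``causal_gene_ids``); QTNs are distributed uniformly without
    replacement over the pooled SNPs of those genes. Effect magnitudes are
    gamma(shape, scale); signs are random +/-1 unless
    ``effects_positive``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if causal_gene_ids is None:
        if n_causal_genes > len(blocks):
            raise GeneGwasError(
                f"n_causal_genes={n_causal_genes} exceeds {len(blocks)} genes"
            )
        chosen = rng.choice(len(blocks), size=n_causal_genes, replace=False)
        causal = [blocks[i] for i in sorted(chosen)]
    else:
        by_id = {b.gene_id: b for b in blocks}
        causal = [by_id[g] for g in causal_gene_ids]
    pool = np.unique(np.concatenate([b.snp_indices for b in causal]))
    if n_qtns > len(pool):
        raise GeneGwasError(
            f"n_qtns={n_qtns} exceeds the {len(pool)} SNPs available in "
            "the causal genes"
        )
    qtn = np.sort(rng.choice(pool, size=n_qtns, replace=False))
    effects = rng.gamma(shape, scale, size=n_qtns)
    if not effects_positive:
        effects *= rng.choice([-1.0, 1.0], size=n_qtns)
    return SimulationTruth(
        causal_gene_ids=[b.gene_id for b in causal],
        qtn_indices=qtn,
        qtn_snp_ids=np.empty(0, dtype=object),  # filled by caller if wanted
        effects=effects,
    )


def simulate_phenotype(panel: GenotypePanel, truth: SimulationTruth,
                       h2_target: float, seed: int | None = None, *,
                       rng: np.random.Generator | None = None
                       ) -> tuple[PhenotypeVector, float]:
    """Phenotype = centered QTN genetic value + scaled Gaussian residual.

    The residual variance is var(g) * (1 - h2) / h2, so the QTN genetic
    values target the stated fraction of phenotypic variance; the realized
    fraction var(g)/var(y) is returned and stored on the truth object.
    """
    if not 0.0 < h2_target < 1.0:
        raise ValueError("h2_target must lie in (0, 1)")
    if truth.qtn_indices.size == 0:
        raise GeneGwasError("truth contains no QTNs")
    if rng is None:
        rng = np.random.default_rng(seed)
    X = panel.imputed()[:, truth.qtn_indices]
    g = X @ truth.effects
    g = g - g.mean()
    var_g = float(np.var(g))
    if var_g <= 0:
        raise GeneGwasError("all QTNs monomorphic: genetic variance is zero")
    e = rng.normal(0.0, np.sqrt(var_g * (1.0 - h2_target) / h2_target),
                   size=len(g))
    y = g + e
    realized = var_g / float(np.var(y))
    truth.qtn_snp_ids = panel.snp_ids[truth.qtn_indices]
    truth.realized_h2 = realized
    pheno = PhenotypeVector(sample_ids=panel.sample_ids, values=y,
                            trait_name="sim_trait")
    return pheno, realized


def simulate_polygenic_phenotype(panel: GenotypePanel,
                                 spectral: SpectralKinship, h2: float,
                                 seed: int | None = None, *,
                                 rng: np.random.Generator | None = None
                                 ) -> PhenotypeVector:
    """Phenotype from the LMM null: y ~ N(0, h2*K + (1-h2)*I).

    Draws g = U diag(sqrt(S)) z with z standard normal (covariance exactly
    K) and adds independent noise; ``h2`` is the model heritability
    sigma_a^2/(sigma_a^2 + sigma_e^2), i.e. sigma_a^2 = h2 and
    sigma_e^2 = 1 - h2. Note that for an inbred panel diag(K) is about 2,
    so the realized population variance fraction of g exceeds h2. With
    h2 = 0 the phenotype is pure noise. Used for calibration and null
    studies in which no individual gene carries a localized effect.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = spectral.n
    if h2 == 0.0:
        y = rng.standard_normal(n)
    else:
        if not 0.0 < h2 < 1.0:
            raise ValueError("h2 must lie in [0, 1)")
        z = rng.standard_normal(n)
        g = spectral.U @ (np.sqrt(spectral.S) * z)
        e = rng.standard_normal(n)
        y = np.sqrt(h2) * g + np.sqrt(1.0 - h2) * e
    return PhenotypeVector(sample_ids=panel.sample_ids, values=y,
                           trait_name="polygenic_sim")


def evaluate_power(scan_result: ScanResult, truth: SimulationTruth,
                   neg_log10_threshold: float) -> tuple[float, float]:
    """(power, type-I error) of one scan against the simulated truth.

    A causal gene is identified (a QTG) when its record passes the
    threshold; power = identified / n_causal_genes. Type-I error is the
    fraction of tested non-causal genes passing the same threshold.
    """
    causal = set(truth.causal_gene_ids)
    n_causal_hit = 0
    n_null = 0
    n_null_hit = 0
    for rec in scan_result.records:
        passing = rec.neg_log10_p >= neg_log10_threshold
        if rec.gene_id in causal:
            n_causal_hit += int(passing)
        else:
            n_null += 1
            n_null_hit += int(passing)
    power = n_causal_hit / len(causal) if causal else 0.0
    type1 = n_null_hit / n_null if n_null else 0.0
    return power, type1


def _scan_cached(yt_one, design_cache, blocks, y, spectral, h2_fixed,
                 method, screen_alpha, h2_upper):
    """EMMAX pass + refinement over pre-rotated designs (power-study core)."""
    import numpy as np

    from .lmm import barebones_fit, weights

    wdiag = weights(spectral.S, h2_fixed)
    sw = np.sqrt(wdiag)
    yt = yt_one / sw
    records = []
    for block, (xt, design) in zip(blocks, design_cache):
        xstar = xt / sw[:, None]
        fit = barebones_fit(yt, xstar, wdiag, h2_fixed)
        records.append(_mkrec(block, design, fit, method, "emmax"))
    # second round: optimize h2 for screened genes
    refined = []
    for block, rec, (xt, design) in zip(blocks, records, design_cache):
        if rec.p > screen_alpha:
            refined.append(rec)
            continue
        h2hat = optimize_h2(y, design.columns, spectral, upper_bound=h2_upper)
        fit = _ProfileObjective(y, design.columns, spectral).fit(h2hat)
        refined.append(_mkrec(block, design, fit, method, "refined"))
    pvals = np.array([r.p for r in refined])
    return ScanResult(
        records=refined, genomic_h2=h2_fixed, n_genes_tested=len(refined),
        bonferroni_neg_log10=bonferroni_threshold(len(refined)),
        gc_lambda=genomic_control_lambda(pvals),
    )


def _mkrec(block, design, fit, method, mode) -> GeneScanRecord:
    from .scan import _record_from_fit

    return _record_from_fit(block, design, fit, method, mode)


def run_power_study(config: SimConfig,
                    methods: tuple[str, ...] = ("ALLSNP", "FPC", "EPC"),
                    qtn_groups: tuple[int, ...] | None = None,
                    thresholds: np.ndarray | None = None,
                    screen_alpha: float = 0.05
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated simulate->scan->evaluate power study.

    Returns (raw, summary): per-replicate rows and mean power / mean
    type-I curves per (QTN group, method, threshold). The genotype panel,
    gene designs, kinship and causal-gene set are fixed across replicates;
    QTN placement, effects and residuals are redrawn each replicate.
    """
    rng = np.random.default_rng(config.seed)
    if qtn_groups is None:
        qtn_groups = (config.n_qtns,)
    panel, catalog = simulate_genotype_panel(config, seed=int(
        rng.integers(2 ** 31)))
    panel = filter_by_maf(panel, 0.05)
    blocks = filter_genes_by_snp_count(
        assign_snps_to_genes(panel, catalog), min_snps=2)
    K = compute_rrm(panel)
    spectral = spectral_decompose(K)
    bonf = bonferroni_threshold(len(blocks))
    if thresholds is None:
        thresholds = np.unique(np.concatenate(
            [np.arange(0.5, 5.01, 0.25), [bonf]]))

    # fixed causal genes, reused across replicates and QTN groups
    causal_idx = rng.choice(len(blocks), size=config.n_causal_genes,
                            replace=False)
    causal_ids = [blocks[i].gene_id for i in sorted(causal_idx)]

    # designs and their rotations are phenotype-independent: build once
    Ut = spectral.U.T
    ones_t = Ut @ np.ones(panel.n_samples)
    caches = {}
    for method in methods:
        cache = []
        for b in blocks:
            d = build_gene_design(b, panel, method.upper())
            xt = np.hstack([ones_t[:, None], Ut @ d.columns])
            cache.append((xt, d))
        caches[method] = cache

    rows = []
    for n_qtns in qtn_groups:
        for rep in range(config.n_reps):
            truth = draw_qtn_architecture(
                blocks, config.n_causal_genes, n_qtns, rng=rng,
                causal_gene_ids=causal_ids,
                shape=config.effect_gamma_shape,
                scale=config.effect_gamma_scale,
                effects_positive=config.effects_positive)
            pheno, realized = simulate_phenotype(
                panel, truth, config.h2_target, rng=rng)
            y = pheno.values
            yt_one = Ut @ y
            gh2 = estimate_genomic_h2(y, spectral)
            for method in methods:
                result = _scan_cached(
                    yt_one, caches[method], blocks, y, spectral, gh2,
                    method.upper(), screen_alpha, max(gh2, 1e-6))
                for thr in thresholds:
                    power, type1 = evaluate_power(result, truth, float(thr))
                    rows.append((n_qtns, method.upper(), float(thr), rep,
                                 power, type1, realized))
    raw = pd.DataFrame(rows, columns=["n_qtns", "method", "threshold",
                                      "rep", "power", "type1",
                                      "realized_h2"])
    grp = raw.groupby(["n_qtns", "method", "threshold"])
    summary = grp.agg(
        mean_power=("power", "mean"), mean_type1=("type1", "mean"),
        se_power=("power", lambda s: s.std(ddof=1) / np.sqrt(len(s))),
    ).reset_index()
    return raw, summary


def power_at_type1(summary: pd.DataFrame, method: str, n_qtns: int,
                   type1_level: float) -> float:
    """Mean power of a method at a matched mean type-I error level.

    Linear interpolation of the (mean_type1, mean_power) curve; clips to
    the observed type-I range.
    """
    sub = summary[(summary["method"] == method.upper())
                  & (summary["n_qtns"] == n_qtns)]
    sub = sub.sort_values("mean_type1")
    x = sub["mean_type1"].to_numpy()
    yv = sub["mean_power"].to_numpy()
    return float(np.interp(type1_level, x, yv))
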