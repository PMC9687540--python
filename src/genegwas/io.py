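"""Readers and writers for the formats the tool touches.

Supported inputs: VCF 4.x (GT fields, biallelic records), GFF3 gene
annotation, a TSV dosage-table dialect, and TSV phenotype tables. The
dosage-table dialect is::

    snp_id  chrom  pos  <sample1>  ...  <sampleN>

one row per SNP, cells in {0, 1, 2, NA}. Scan results are written as TSV
with a fixed column order (see :func:`write_scan_results`).

Coordinates are 1-based inclusive in both VCF and GFF3; no conversion is
performed anywhere.
"""

from __future__ import annotations

import logging
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .errors import EmptyPanelError, GeneGwasError, ParseError
from .panel import GeneCatalog, GenotypePanel, PhenotypeVector, allele_frequencies

if TYPE_CHECKING:  # pragma: no cover
    from .scan import GeneScanRecord

logger = logging.getLogger(__name__)

#: Exact column order of the scan-results TSV.
SCAN_RESULT_COLUMNS = [
    "gene_id", "chrom", "start", "end", "n_snps", "df_beta", "h2",
    "beta_norm", "sigma2e", "F", "p", "neg_log10_p", "method", "mode",
]


def read_vcf_dosages(path: str, maf_min: float = 0.0) -> GenotypePanel:
    """Read a VCF into a :class:`GenotypePanel` of ALT-allele dosages.

    Only biallelic records are used; multiallelic records are skipped and
    counted in the log. Missing genotypes (``./.``) become NaN. SNPs whose
    minor-allele frequency falls below ``maf_min`` (or whose genotypes are
    all missing) are dropped.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise OSError(f"cannot read VCF {path!r}: {exc}") from exc

    sample_ids = list(vcf.samples)
    snp_ids, chroms, poss, rows = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        dos = np.empty(len(gts))
        for i, gt in enumerate(gts):
            alleles = [a for a in gt[:-1] if a is not None]
            if not alleles or any(a < 0 for a in alleles):
                dos[i] = np.nan
            else:
                dos[i] = float(sum(1 for a in alleles if a > 0))
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        rows.append(dos)
    if n_multi:
        logger.info("skipped %d multiallelic VCF record(s)", n_multi)
    if not rows:
        raise EmptyPanelError(f"no usable biallelic records in {path!r}")

    dosage = np.vstack(rows).T  # samples x SNPs
    panel = GenotypePanel(
        sample_ids=np.array(sample_ids, dtype=object),
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        dosage=dosage,
    )
    panel = _drop_all_missing(panel)
    if maf_min > 0:
        f = panel.allele_freq
        keep = np.minimum(f, 1.0 - f) >= maf_min
        panel = panel.take_snps(keep)
    if panel.n_snps == 0:
        raise EmptyPanelError(f"no SNPs survive MAF >= {maf_min} in {path!r}")
    return panel


def _drop_all_missing(panel: GenotypePanel) -> GenotypePanel:
    all_missing = np.isnan(panel.dosage).all(axis=0)
    if all_missing.any():
        dropped = panel.snp_ids[all_missing]
        logger.warning(
            "dropping %d SNP(s) with all genotypes missing: %s",
            all_missing.sum(), ", ".join(map(str, dropped[:10])),
        )
        panel = panel.take_snps(~all_missing)
    return panel


def read_dosage_table(path: str) -> GenotypePanel:
    """Read the TSV dosage dialect (header: snp_id chrom pos <samples...>)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[:3] != ["snp_id", "chrom", "pos"]:
            raise ParseError(
                f"{path}: header must start with 'snp_id\\tchrom\\tpos', got {cols[:3]}"
            )
        sample_ids = cols[3:]
        n = len(sample_ids)
        snp_ids, chroms, poss, rows = [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 3 + n:
                raise ParseError(
                    f"{path}: line {lineno}: expected {3 + n} fields, got {len(cells)}"
                )
            snp_ids.append(cells[0])
            chroms.append(cells[1])
            try:
                poss.append(int(cells[2]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad position {cells[2]!r}") from exc
            row = np.empty(n)
            for j, cell in enumerate(cells[3:]):
                if cell == "NA":
                    row[j] = np.nan
                else:
                    try:
                        row[j] = float(cell)
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}: line {lineno}: non-numeric dosage {cell!r}"
                        ) from exc
            rows.append(row)
    if not rows:
        raise EmptyPanelError(f"{path}: no SNP rows")
    panel = GenotypePanel(
        sample_ids=np.array(sample_ids, dtype=object),
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        dosage=np.vstack(rows).T,
    )
    return _drop_all_missing(panel)


def write_dosage_table(panel: GenotypePanel, path: str) -> None:
    """Write a panel in the TSV dosage dialect (inverse of read_dosage_table)."""
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\t" + "\t".join(map(str, panel.sample_ids)) + "\n")
        D = panel.dosage
        for j in range(panel.n_snps):
            cells = [
                "NA" if np.isnan(v) else ("%g" % v)
                for v in D[:, j]
            ]
            fh.write(
                f"{panel.snp_ids[j]}\t{panel.chrom[j]}\t{panel.pos[j]}\t"
                + "\t".join(cells) + "\n"
            )


def read_gff3_genes(path: str, feature_type: str = "gene") -> GeneCatalog:
    """Extract gene records from a GFF3 annotation file.

    Keeps only rows whose feature (column 3) equals ``feature_type``;
    gene_id is taken from the ``ID=`` attribute. Records lacking an ID are
    skipped with a warning; duplicate IDs raise an error.
    """
    gene_ids, chroms, starts, ends, strands = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"{path}: line {lineno}: GFF3 requires 9 columns, got {len(fields)}"
                )
            if fields[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID")
            if gid is None:
                logger.warning("%s: line %d: %s record without ID attribute skipped",
                               path, lineno, feature_type)
                continue
            gene_ids.append(gid)
            chroms.append(fields[0])
            try:
                starts.append(int(fields[3]))
                ends.append(int(fields[4]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad coordinates") from exc
            strands.append(fields[6])
    return GeneCatalog(
        gene_id=np.array(gene_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        strand=np.array(strands, dtype=object),
    )


def write_gff3_genes(catalog: GeneCatalog, path: str, source: str = "genegwas") -> None:
    """Write a catalog as minimal GFF3 gene records."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i in range(len(catalog)):
            fh.write(
                f"{catalog.chrom[i]}\t{source}\tgene\t{catalog.start[i]}\t"
                f"{catalog.end[i]}\t.\t{catalog.strand[i]}\t.\tID={catalog.gene_id[i]}\n"
            )


def read_phenotypes(path: str, trait_name: str) -> PhenotypeVector:
    """Read one trait column from a TSV phenotype table.

    The first column is the sample ID; rows with a missing trait value are
    dropped (and counted in the log). Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if trait_name not in df.columns[1:]:
        raise GeneGwasError(
            f"trait {trait_name!r} not found; available: "
            + ", ".join(df.columns[1:])
        )
    vals = pd.to_numeric(df[trait_name], errors="coerce")
    keep = vals.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d sample(s) with missing %s", n_dropped, trait_name)
    if not keep.any():
        raise GeneGwasError(f"all values of trait {trait_name!r} are missing")
    return PhenotypeVector(
        sample_ids=df.iloc[:, 0][keep].to_numpy(dtype=object),
        values=vals[keep].to_numpy(dtype=np.float64),
        trait_name=trait_name,
    )


def write_phenotypes(pheno: PhenotypeVector, path: str) -> None:
    """Write a phenotype vector as a two-column TSV."""
    pd.DataFrame(
        {"sample_id": pheno.sample_ids, pheno.trait_name: pheno.values}
    ).to_csv(path, sep="\t", index=False)


def _fmt6(x: float) -> str:
    return "%.6g" % x


def write_scan_results(records: Iterable["GeneScanRecord"], path: str) -> None:
    """Write gene-scan records as TSV with the fixed column order.

    Floats are formatted at 6 significant digits.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(SCAN_RESULT_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join([
                str(r.gene_id), str(r.chrom), str(r.start), str(r.end),
                str(r.n_snps), str(r.df_beta), _fmt6(r.h2_used),
                _fmt6(r.beta_norm), _fmt6(r.sigma2e), _fmt6(r.F),
                _fmt6(r.p), _fmt6(r.neg_log10_p), r.method, r.mode,
            ]) + "\n")


def read_scan_results(path: str) -> pd.DataFrame:
    """Read a scan-results TSV back into a DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SCAN_RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing result columns: {missing}")
    return df
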