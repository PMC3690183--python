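"""Readers and writers for the file formats the pipeline touches.

Text formats only: VCF (one pseudo-chromosome), PLINK .ped/.map, GCTA-style
``.phen`` (FID IID VALUE, whitespace-delimited, "NA" for missing),
covariate TSV (FID IID then columns), the twin-pair TSV, and the GCTA text
GRM triplet format (``.grm.gz`` + ``.grm.id``).  VCF files are read back
with cyvcf2; the simple writers are plain-text emitters since no installed
library writes these formats directly.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .grm import GRM

__all__ = [
    "write_vcf", "read_vcf", "write_plink", "read_plink",
    "write_phen", "read_phen", "write_covar", "read_covar",
    "write_twin_tsv", "read_twin_tsv", "write_grm", "read_grm",
]

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCFv4.2 with GT genotypes on chromosome 1."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, genotypes.sample_ids)) + "\n")
        for j in range(genotypes.n_snps):
            gts = "\t".join(
                _GT.get(genotypes.dosages[i, j], "./.") for i in range(genotypes.n_individuals)
            )
            fh.write(f"1\t{genotypes.positions[j]}\t{genotypes.snp_ids[j]}\t"
                     f"{genotypes.ref[j]}\t{genotypes.alt[j]}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic VCF into a dosage matrix (alt-allele counts)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    rows, ids, pos, ref, alt = [], [], [], [], []
    for var in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(3 in cyvcf2), 2=unknown
        d = np.array(var.gt_types, dtype=float)
        dos = np.where(d == 0, 0.0, np.where(d == 1, 1.0, np.where(d == 3, 2.0, np.nan)))
        rows.append(dos)
        ids.append(var.ID)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0] if var.ALT else ".")
    return GenotypeMatrix(
        dosages=np.array(rows).T, snp_ids=np.array(ids), positions=np.array(pos),
        ref=np.array(ref), alt=np.array(alt), sample_ids=samples,
    )


def write_plink(genotypes: GenotypeMatrix, prefix) -> None:
    """Write PLINK text .ped/.map (alleles ref/alt, missing = '0 0')."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(genotypes.n_snps):
            fh.write(f"1\t{genotypes.snp_ids[j]}\t0\t{genotypes.positions[j]}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(genotypes.n_individuals):
            fields = [str(genotypes.family_ids[i]), str(genotypes.sample_ids[i]),
                      "0", "0", "0", "-9"]
            for j in range(genotypes.n_snps):
                d = genotypes.dosages[i, j]
                r, a = genotypes.ref[j], genotypes.alt[j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [r, r]
                elif d == 1:
                    fields += [r, a]
                else:
                    fields += [a, a]
            fh.write(" ".join(fields) + "\n")


def read_plink(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    mp = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                     names=["chrom", "snp", "cm", "pos"], dtype={"snp": str})
    fam, iid, rows = [], [], []
    alleles = [set() for _ in range(len(mp))]
    raw = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            fam.append(parts[0])
            iid.append(parts[1])
            pairs = list(zip(parts[6::2], parts[7::2]))
            raw.append(pairs)
            for j, (x, y) in enumerate(pairs):
                alleles[j].update(a for a in (x, y) if a != "0")
    ref, alt = [], []
    for s in alleles:
        srt = sorted(s)
        ref.append(srt[0] if srt else "A")
        alt.append(srt[1] if len(srt) > 1 else ".")
    for pairs in raw:
        row = []
        for j, (x, y) in enumerate(pairs):
            if x == "0" or y == "0":
                row.append(np.nan)
            else:
                row.append(float((x == alt[j]) + (y == alt[j])))
        rows.append(row)
    return GenotypeMatrix(
        dosages=np.array(rows), snp_ids=mp["snp"].to_numpy(),
        positions=mp["pos"].to_numpy(), ref=np.array(ref), alt=np.array(alt),
        sample_ids=np.array(iid), family_ids=np.array(fam),
    )


def write_phen(table: pd.DataFrame, path, value_col: str) -> None:
    """Write FID IID VALUE, whitespace-delimited, missing as NA."""
    with open(path, "w") as fh:
        for _, row in table.iterrows():
            v = row[value_col]
            val = "NA" if pd.isna(v) else f"{v:.10g}"
            fh.write(f"{row['fid']} {row['iid']} {val}\n")


def read_phen(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["fid", "iid", "value"],
                     dtype={"fid": str, "iid": str}, na_values=["NA", "-9"])
    return df


def write_covar(table: pd.DataFrame, path, columns) -> None:
    """Covariate TSV: FID IID then the named columns."""
    out = table[["fid", "iid", *columns]]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_covar(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"fid": str, "iid": str}, na_values=["NA"])


def write_twin_tsv(table: pd.DataFrame, path) -> None:
    cols = ["pair_id", "zygosity", "t1_twin1", "t2_twin1", "t1_twin2", "t2_twin2"]
    table[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_twin_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"pair_id": str, "zygosity": str},
                       na_values=["NA"])


def write_grm(grm: GRM, prefix) -> None:
    """GCTA text triplet format: ``<prefix>.grm.gz`` lines of
    ``i j n_snps value`` (1-based, lower triangle) plus ``<prefix>.grm.id``."""
    prefix = str(prefix)
    with gzip.open(prefix + ".grm.gz", "wt") as fh:
        for i in range(grm.n_individuals):
            for j in range(i + 1):
                # 17 significant digits round-trips IEEE doubles bit-exactly
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_snps[i, j]}\t"
                         f"{grm.values[i, j]:.17g}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for f, s in zip(grm.family_ids, grm.sample_ids):
            fh.write(f"{f}\t{s}\n")


def read_grm(prefix) -> GRM:
    prefix = str(prefix)
    ids = pd.read_csv(prefix + ".grm.id", sep="\t", header=None, names=["fid", "iid"],
                      dtype=str)
    n = len(ids)
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    with gzip.open(prefix + ".grm.gz", "rt") as fh:
        for line in fh:
            i, j, m, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            values[i, j] = values[j, i] = float(v)
            counts[i, j] = counts[j, i] = int(m)
    return GRM(values=values, n_snps=counts, sample_ids=ids["iid"].to_numpy(),
               family_ids=ids["fid"].to_numpy())
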