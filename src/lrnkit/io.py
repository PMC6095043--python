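"""Readers and writers for the package's plain-text interchange formats.

Matrices travel as TSV with a header row of sample identifiers and a first
column of feature identifiers. Interval sets arrive as BED (0-based
half-open, converted to the 1-based inclusive convention used internally),
gene sets as GMT, genotypes as dosage TSV or VCF.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_annotations_tsv",
    "read_bed",
    "read_gmt",
    "write_vcf",
    "read_vcf_dosages",
]


def read_matrix_tsv(path) -> pd.DataFrame:
    """Features × samples matrix: header = samples, first column = ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_annotations_tsv(path) -> pd.DataFrame:
    """Feature annotation table with at least chrom and position columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"chrom", "position"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_bed(path) -> pd.DataFrame:
    """BED intervals converted to 1-based inclusive [start, end].

    Returns columns chrom, start, end, name (name optional in the file),
    plus `center`, the midpoint used for center-overlap assignment.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{end0}"
            rows.append((chrom, start0 + 1, end0, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    df["center"] = (df["start"] + df["end"]) // 2
    return df


def read_gmt(path) -> dict:
    """GMT gene sets: name<TAB>description<TAB>gene1<TAB>gene2…"""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_vcf(genotypes, path) -> None:
    """Export a GenotypeMatrix as a minimal VCFv4.2 with GT calls.

    Dosages 0/1/2 become 0/0, 0/1, 1/1; fractional dosages are rounded.
    """
    dos = genotypes.dosages
    annot = genotypes.annotations
    samples = list(dos.columns)
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(str(c) for c in annot["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp in dos.index:
            chrom = annot.loc[snp, "chrom"]
            pos = int(annot.loc[snp, "position"])
            calls = [gt_of[int(round(v))] for v in dos.loc[snp]]
            fh.write(f"{chrom}\t{pos}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_vcf_dosages(path):
    """Read a VCF into a dosage DataFrame plus an annotation table.

    Uses cyvcf2 when available, else a plain-text GT parser (unphased or
    phased diploid calls; missing alleles become NaN).
    """
    try:
        from cyvcf2 import VCF
    except ImportError:
        VCF = None
    if VCF is not None:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        ids, chroms, poss, rows = [], [], [], []
        for var in vcf:
            ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            chroms.append(str(var.CHROM))
            poss.append(var.POS)
            # gt_types codes: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gts = np.asarray(var.gt_types, dtype=float)
            gts[gts == 2] = np.nan
            gts[gts == 3] = 2.0
            rows.append(gts)
        dos = pd.DataFrame(rows, index=ids, columns=samples)
    else:
        ids, chroms, poss, rows, samples = [], [], [], [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    samples = parts[9:]
                    continue
                chroms.append(parts[0])
                poss.append(int(parts[1]))
                ids.append(parts[2])
                row = []
                for call in parts[9:]:
                    gt = call.split(":")[0].replace("|", "/")
                    alleles = gt.split("/")
                    if "." in alleles:
                        row.append(np.nan)
                    else:
                        row.append(sum(int(a) > 0 for a in alleles))
                rows.append(row)
        dos = pd.DataFrame(rows, index=ids, columns=samples, dtype=float)
    annot = pd.DataFrame({"chrom": chroms, "position": poss},
                         index=pd.Index(ids, name="snp"))
    return dos, annot
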