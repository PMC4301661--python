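"""Read/write genotype matrices in VCF, PLINK binary and plain-TSV form.

All readers return minor/ALT-allele dosage codes {0, 1, 2} with -1 for a
missing call, individuals in rows.  ``read_genotypes(write_genotypes(x))``
is the identity on codes for every supported format.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .io_plink import read_plink, write_plink

MISSING = -1
FORMATS = ("vcf", "plink", "tsv")


class GenotypeParseError(ValueError):
    """Malformed genotype file; message carries the offending record."""


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(path: str | pathlib.Path, fmt: str, G: np.ndarray,
                    sample_ids, snp_ids, chrom, pos) -> None:
    path = pathlib.Path(path)
    if fmt == "tsv":
        _write_tsv(path, G, sample_ids, snp_ids, chrom, pos)
    elif fmt == "vcf":
        _write_vcf(path, G, sample_ids, snp_ids, chrom, pos)
    elif fmt == "plink":
        write_plink(path.with_suffix(""), G, sample_ids, snp_ids, chrom, pos)
    else:
        raise ValueError(f"unknown format {fmt!r}; supported: {', '.join(FORMATS)}")


def read_genotypes(path: str | pathlib.Path, fmt: str):
    """Returns (G, sample_ids, snp_ids, chrom, pos)."""
    path = pathlib.Path(path)
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "plink":
        return read_plink(path.with_suffix(""))
    raise ValueError(f"unknown format {fmt!r}; supported: {', '.join(FORMATS)}")


# ---------------------------------------------------------------------------
# TSV: rows = individuals, columns = SNPs, codes 0/1/2, "NA" missing.
# SNP positions live in a sidecar <name>.snps.tsv (snp_id, chrom, pos).


def _sidecar(path: pathlib.Path) -> pathlib.Path:
    return path.with_suffix(".snps.tsv")


def _write_tsv(path, G, sample_ids, snp_ids, chrom, pos) -> None:
    df = pd.DataFrame(G, index=pd.Index(sample_ids, name="iid"), columns=snp_ids)
    df = df.astype(object).mask(df == MISSING, "NA")
    df.to_csv(path, sep="\t")
    pd.DataFrame({"snp_id": snp_ids, "chrom": chrom, "pos": pos}).to_csv(
        _sidecar(path), sep="\t", index=False)


def _read_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    snp_ids = list(df.columns)
    if len(set(snp_ids)) != len(snp_ids):
        raise GenotypeParseError("duplicate SNP id in TSV header")
    vals = df.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"invalid genotype code {vals[i, j]!r} at row {i + 2}, SNP {snp_ids[j]}")
    G = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
    side = _sidecar(path)
    if side.exists():
        meta = pd.read_csv(side, sep="\t")
        chrom = meta["chrom"].to_numpy()
        pos = meta["pos"].to_numpy()
    else:
        chrom = np.ones(len(snp_ids), dtype=int)
        pos = np.arange(1, len(snp_ids) + 1)
    return G, list(df.index.astype(str)), snp_ids, chrom, pos


# ---------------------------------------------------------------------------
# VCF: one sample column per individual, GT-only FORMAT, ALT = counted allele.


def _write_vcf(path, G, sample_ids, snp_ids, chrom, pos,
               ref: str = "A", alt: str = "C") -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hetsurv\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in sample_ids) + "\n")
        for j, sid in enumerate(snp_ids):
            gts = "\t".join(_GT_STRING[int(g)] for g in G[:, j])
            fh.write(f"{chrom[j]}\t{pos[j]}\t{sid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    rows, snp_ids, chrom, pos = [], [], [], []
    seen = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeParseError(
                f"multi-allelic record not supported: {rec.ID} at "
                f"{rec.CHROM}:{rec.POS} (ALT={rec.ALT})")
        sid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if sid in seen:
            raise GenotypeParseError(f"duplicate SNP id {sid!r}")
        seen.add(sid)
        snp_ids.append(sid)
        chrom.append(_chrom_token(rec.CHROM))
        pos.append(rec.POS)
        gt = rec.gt_types.astype(np.int8)  # gts012: 0,1,2; 3 = unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    if not rows:
        raise GenotypeParseError("VCF contains no variant records")
    G = np.stack(rows, axis=1)
    return G, sample_ids, snp_ids, np.array(chrom, dtype=object), np.array(pos)


def _chrom_token(token: str):
    token = token.removeprefix("chr")
    try:
        return int(token)
    except ValueError:
        return token
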