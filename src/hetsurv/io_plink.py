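"""Minimal PLINK 1 binary (.bed/.bim/.fam) codec.

Implements the SNP-major 2-bit .bed layout: 3 magic bytes
(0x6c, 0x1b, 0x01) followed by ceil(n/4) bytes per SNP, first sample in
the lowest-order bit pair.  Bit-pair coding: 00 = homozygous A1,
01 = missing, 10 = heterozygous, 11 = homozygous A2.  We write A1 as the
counted (minor) allele, so dosage 2 maps to 00 and dosage 0 to 11.
"""

from __future__ import annotations

import pathlib

import numpy as np

MAGIC = bytes([0x6C, 0x1B, 0x01])
MISSING = -1

# dosage (minor-allele count) -> bit pair, A1 = minor allele
_DOSAGE_TO_BITS = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_BITS_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


class PlinkFormatError(ValueError):
    pass


def write_plink(prefix: str | pathlib.Path, G: np.ndarray, sample_ids,
                snp_ids, chrom, pos, a1: str = "C", a2: str = "A") -> None:
    """Write genotypes (individuals x SNPs, minor-allele dosage) to
    ``prefix``.bed/.bim/.fam."""
    prefix = pathlib.Path(prefix)
    n, m = G.shape
    lut = np.zeros(4, dtype=np.uint8)
    for dosage, bits in _DOSAGE_TO_BITS.items():
        lut[dosage % 4] = bits  # MISSING=-1 -> index 3
    codes = lut[G.astype(np.int64) % 4].astype(np.uint8)  # n x m bit pairs

    nbytes = (n + 3) // 4
    padded = np.zeros((m, nbytes * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    shifts = np.tile([0, 2, 4, 6], nbytes)
    packed = np.bitwise_or.reduce(
        (padded << shifts).reshape(m, nbytes, 4), axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(MAGIC)
        fh.write(packed.tobytes())

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(m):
            fh.write(f"{chrom[j]}\t{snp_ids[j]}\t0\t{pos[j]}\t{a1}\t{a2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid in sample_ids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")


def read_plink(prefix: str | pathlib.Path):
    """Read ``prefix``.bed/.bim/.fam; returns (G, sample_ids, snp_ids,
    chrom, pos) with G coded as A1 (minor-allele) dosage, MISSING = -1."""
    prefix = pathlib.Path(prefix)
    fam = [line.split() for line in
           prefix.with_suffix(".fam").read_text().splitlines() if line.strip()]
    sample_ids = [row[1] for row in fam]
    bim = [line.split() for line in
           prefix.with_suffix(".bim").read_text().splitlines() if line.strip()]
    snp_ids = [row[1] for row in bim]
    if len(set(snp_ids)) != len(snp_ids):
        raise PlinkFormatError("duplicate SNP id in .bim")
    chrom = np.array([_parse_chrom(row[0]) for row in bim])
    pos = np.array([int(row[3]) for row in bim])

    n, m = len(sample_ids), len(snp_ids)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != MAGIC:
        raise PlinkFormatError(".bed magic bytes missing or not SNP-major")
    nbytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * nbytes:
        raise PlinkFormatError(".bed size inconsistent with .bim/.fam")
    body = body.reshape(m, nbytes)
    pairs = np.stack([(body >> s) & 0b11 for s in (0, 2, 4, 6)], axis=2)
    pairs = pairs.reshape(m, nbytes * 4)[:, :n]
    G = _BITS_TO_DOSAGE[pairs].T.copy()
    return G, sample_ids, snp_ids, chrom, pos


def _parse_chrom(token: str):
    try:
        return int(token)
    except ValueError:
        return token
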