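"""SNP-level quality control.

Applies the study's exclusion rules to a genotype matrix: monomorphic
SNPs, call-rate (missingness > 0.5%), minor-allele frequency (MAF <= 10%),
Hardy–Weinberg disequilibrium (p < 0.001 by default; the literal
"exclude when HWE p >= 0.001" reading is available behind a flag),
non-autosomal SNPs, and an optional external exclusion list standing in
for annotation-based removals (non-unique genome mapping, retired array
probes).  A SNP may fail several rules; the exclusion report counts each.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_genotypes import MISSING, read_genotypes as _read_raw

AUTOSOMES = set(range(1, 23)) | {str(c) for c in range(1, 23)}

REASONS = ("monomorphic", "missingness", "maf", "hwe", "non-autosomal",
           "exclusion-list")


@dataclass
class QCThresholds:
    """Exclusion thresholds. Boundary semantics follow the printed rules:
    missing fraction strictly greater than ``max_missing`` excludes
    (exactly 0.5% is retained); ``maf <= maf_exclusive_min`` excludes
    (exactly 10% is excluded)."""

    max_missing: float = 0.005
    maf_exclusive_min: float = 0.10
    hwe_min_p: float = 0.001
    literal_hwe_rule: bool = False  # exclude hwe_p >= threshold, as printed

    def validate(self) -> None:
        for v in (self.max_missing, self.maf_exclusive_min, self.hwe_min_p):
            if not (0.0 <= v <= 1.0):
                raise ValueError("QC thresholds must lie in [0, 1]")


def read_genotypes(path: str | pathlib.Path, fmt: str):
    """Read a genotype file and build its SNP panel.

    Returns ``(G, panel)`` where ``G`` is individuals x SNPs minor-allele
    dosage (-1 missing) and ``panel`` is the per-SNP metadata frame.
    """
    G, sample_ids, snp_ids, chrom, pos = _read_raw(path, fmt)
    panel = build_panel(G, snp_ids, chrom, pos)
    return G, sample_ids, panel


def allele_frequencies(G: np.ndarray) -> pd.DataFrame:
    """Per-SNP allele frequencies from dosage codes.

    frequency = minor-allele count / (2 x non-missing individuals);
    ``p_major >= 0.5`` is enforced by orientation (a column whose coded
    allele turns out to be the major one is re-oriented, so a (2,2,2)
    column reports maf 0).  All-missing SNPs get NaN frequencies and are
    flagged in the ``defined`` column.
    """
    G = np.asarray(G)
    obs = G != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coded_freq = np.where(obs, G, 0).sum(axis=0) / (2.0 * n_obs)
    maf = np.minimum(coded_freq, 1.0 - coded_freq)
    p_major = 1.0 - maf
    call_rate = n_obs / G.shape[0]
    # computed from the count directly so a 1/200 missing fraction compares
    # exactly equal to a 0.005 threshold (1 - call_rate would not)
    missing_rate = (G.shape[0] - n_obs) / G.shape[0]
    return pd.DataFrame({
        "coded_freq": coded_freq, "maf": maf, "p_major": p_major,
        "call_rate": call_rate, "missing_rate": missing_rate,
        "defined": n_obs > 0,
    })


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "chisq") -> float:
    """Hardy–Weinberg goodness-of-fit p-value from genotype counts.

    Default is the 1-df chi-square test against expected counts
    {n p^2, 2 n p q, n q^2} at the sample allele frequency; ``method=
    "exact"`` uses the conditional exact test (sum of het-count
    probabilities no larger than the observed one).  Monomorphic counts
    return NaN — there is nothing to test.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("HWE test undefined for zero total count")
    p = (2 * n_AA + n_Aa) / (2.0 * n)
    if p in (0.0, 1.0):
        return float("nan")
    if method == "chisq":
        q = 1.0 - p
        expected = n * np.array([p * p, 2 * p * q, q * q])
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(int(n_AA), int(n_Aa), int(n_aa))
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Conditional exact HWE test (probabilities conditional on the minor
    allele count), two-sided by summing outcomes at most as probable."""
    from scipy.special import gammaln

    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    logp = (gammaln(n + 1) - gammaln(hom_min + 1) - gammaln(hets + 1)
            - gammaln(hom_maj + 1) + hets * np.log(2.0)
            + gammaln(n_minor + 1) + gammaln(2 * n - n_minor + 1)
            - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[np.nonzero(hets == n_Aa)[0][0]]
    return float(probs[probs <= observed * (1 + 1e-12)].sum())


def genotype_counts(G: np.ndarray, coded_freq: np.ndarray) -> np.ndarray:
    """Per-SNP (hom-major, het, hom-minor) counts, orientation-aware."""
    n0 = (G == 0).sum(axis=0)
    n1 = (G == 1).sum(axis=0)
    n2 = (G == 2).sum(axis=0)
    flip = coded_freq > 0.5  # coded allele is actually the major one
    hom_major = np.where(flip, n2, n0)
    hom_minor = np.where(flip, n0, n2)
    return np.stack([hom_major, n1, hom_minor], axis=1)


def _hwe_chisq_vector(counts: np.ndarray) -> np.ndarray:
    """Vectorized 1-df chi-square HWE p-values from (hom-major, het,
    hom-minor) count rows; NaN where the test is undefined (monomorphic
    or empty).  Same statistic as :func:`hwe_test` with method="chisq"."""
    counts = counts.astype(float)
    n = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * counts[:, 0] + counts[:, 1]) / (2 * n)
        q = 1.0 - p
        expected = n[:, None] * np.stack([p * p, 2 * p * q, q * q], axis=1)
        chi2 = ((counts - expected) ** 2 / expected).sum(axis=1)
        out = stats.chi2.sf(chi2, df=1)
    out[(n == 0) | (p <= 0) | (p >= 1)] = np.nan
    return out


def build_panel(G: np.ndarray, snp_ids, chrom, pos,
                ref: str = "A", alt: str = "C") -> pd.DataFrame:
    """Assemble the per-SNP metadata frame (frequencies, call rate, HWE)."""
    freqs = allele_frequencies(G)
    counts = genotype_counts(G, freqs["coded_freq"].to_numpy())
    hwe_p = _hwe_chisq_vector(counts)
    return pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": np.asarray(chrom, dtype=object),
        "pos": np.asarray(pos),
        "ref": ref, "alt": alt,
        "p_major": freqs["p_major"],
        "maf": freqs["maf"],
        "call_rate": freqs["call_rate"],
        "missing_rate": freqs["missing_rate"],
        "hwe_p": hwe_p,
    })


def is_autosomal(chrom) -> np.ndarray:
    return np.array([c in AUTOSOMES for c in np.asarray(chrom, dtype=object)])


def filter_snps(G: np.ndarray, panel: pd.DataFrame,
                thresholds: QCThresholds | None = None,
                exclusion_list: set | None = None):
    """Apply all SNP exclusion rules.

    A SNP survives iff it is polymorphic, its missing fraction is at most
    ``max_missing``, maf strictly exceeds ``maf_exclusive_min``, the HWE
    p-value clears the rule, the chromosome is autosomal (1–22) and the id
    is not on the exclusion list.  Returns ``(G_f, panel_f, report)``
    where ``report`` has one row per excluded SNP with its
    semicolon-joined reasons.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    if len(panel) != G.shape[1]:
        raise ValueError("panel and genotype matrix are not aligned")
    exclusion_list = exclusion_list or set()

    maf = panel["maf"].to_numpy(dtype=float)
    miss = panel["missing_rate"].to_numpy(dtype=float)
    hwe = panel["hwe_p"].to_numpy(dtype=float)

    fails = {
        "monomorphic": ~(maf > 0.0),  # includes all-missing (maf NaN)
        "missingness": miss > thresholds.max_missing,
        "maf": (maf <= thresholds.maf_exclusive_min) & (maf > 0.0),
        "non-autosomal": ~is_autosomal(panel["chrom"]),
        "exclusion-list": panel["snp_id"].isin(exclusion_list).to_numpy(),
    }
    with np.errstate(invalid="ignore"):
        if thresholds.literal_hwe_rule:
            fails["hwe"] = (hwe >= thresholds.hwe_min_p) & ~np.isnan(hwe)
        else:
            fails["hwe"] = (hwe < thresholds.hwe_min_p) & ~np.isnan(hwe)

    any_fail = np.zeros(len(panel), dtype=bool)
    for mask in fails.values():
        any_fail |= mask

    reasons = []
    for j in np.nonzero(any_fail)[0]:
        rs = [r for r in REASONS if r in fails and fails[r][j]]
        reasons.append({"snp_id": panel["snp_id"].iat[j], "reasons": ";".join(rs)})
    report = pd.DataFrame(reasons, columns=["snp_id", "reasons"])

    keep = ~any_fail
    panel_f = panel.loc[keep].reset_index(drop=True).copy()
    panel_f["qc_pass"] = True
    return G[:, keep], panel_f, report


def reason_counts(report: pd.DataFrame) -> pd.Series:
    """Number of excluded SNPs per failure reason (multi-reason counted in
    each)."""
    if report.empty:
        return pd.Series(dtype=int)
    return report["reasons"].str.split(";").explode().value_counts()
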