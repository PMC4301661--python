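"""The HWE-normalized multilocus heterozygosity statistic.

For an individual with genotype codes g_m over QC-passed autosomal SNPs,

    t = (# heterozygous loci) / sum_m 2 p_m (1 - p_m)

with p_m the cohort major-allele frequency.  The denominator is the
Hardy–Weinberg expectation of the numerator, so E[t] ~ 1 under random
mating, and the statistic up-weights loci where heterozygosity is a
priori unlikely (low minor-allele frequency).  Both sums run over the
individual's non-missing loci only, which keeps E[t] = 1 under
missingness-at-random.

The cohort SD of t is the bridging quantity for the meta-analysis: it
shrinks like 1/sqrt(M) with panel size M, and multiplying a Cox log-HR on
t by SD(t) yields the array-size-comparable per-SD effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_genotypes import MISSING


def expected_het(p_major: np.ndarray) -> np.ndarray:
    """Per-SNP HWE heterozygosity expectation 2 p (1 - p); symmetric in
    p vs 1 - p, so major/minor orientation does not matter."""
    p = np.asarray(p_major, dtype=float)
    return 2.0 * p * (1.0 - p)


def het_scores(G: np.ndarray, p_major: np.ndarray,
               iids=None, scope: str = "genome") -> pd.DataFrame:
    """Heterozygosity statistic for every individual (rows of ``G``).

    Returns a frame with iid, scope, n_loci_used, n_het,
    expected_het_sum and t; individuals with no usable locus get t = NaN
    and ``defined = False``.
    """
    G = np.atleast_2d(G)
    e = expected_het(p_major)
    if G.shape[1] != e.shape[0]:
        raise ValueError("genotypes and frequencies are not aligned")
    obs = G != MISSING
    n_het = ((G == 1) & obs).sum(axis=1)
    denom = np.where(obs, e[None, :], 0.0).sum(axis=1)
    n_loci = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, n_het / denom, np.nan)
    if iids is None:
        iids = np.arange(G.shape[0])
    return pd.DataFrame({
        "iid": iids, "scope": scope, "n_loci_used": n_loci, "n_het": n_het,
        "expected_het_sum": denom, "t": t, "defined": denom > 0,
    })


def het_score(genotype_row: np.ndarray, p_major: np.ndarray) -> float:
    """t for a single individual (convenience scalar form)."""
    return float(het_scores(genotype_row[None, :], p_major)["t"].iloc[0])


def het_scores_by_chromosome(G: np.ndarray, chrom: np.ndarray,
                             p_major: np.ndarray, iids=None) -> pd.DataFrame:
    """Per-chromosome recomputation of t (only SNPs of one chromosome at a
    time).  Chromosomes with zero SNPs are omitted.  Numerators across
    chromosomes sum to the genome-wide numerator by construction."""
    chrom = np.asarray(chrom)
    frames = []
    for c in pd.unique(chrom):
        cols = chrom == c
        frames.append(het_scores(G[:, cols], p_major[cols], iids=iids,
                                 scope=f"chr{c}"))
    return pd.concat(frames, ignore_index=True)


def standardize_scores(t: np.ndarray) -> pd.DataFrame:
    """Within-cohort z-scores of t using the sample (n-1) SD.

    Raises on fewer than two defined values or a degenerate (constant)
    cohort.
    """
    t = np.asarray(t, dtype=float)
    ok = ~np.isnan(t)
    if ok.sum() < 2:
        raise ValueError("need at least two defined heterozygosity scores")
    mean = t[ok].mean()
    sd = t[ok].std(ddof=1)
    if sd == 0:
        raise ValueError("constant heterozygosity; cohort is degenerate")
    z = (t - mean) / sd
    return pd.DataFrame({"t": t, "z": z, "cohort_mean": mean, "cohort_sd": sd})
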