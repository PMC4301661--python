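"""Sample-level quality control.

Population-structure handling for the survival analysis: genotype
standardization, PCA of the combined study + reference matrix, genetic
outlier exclusion by explained-variance-weighted Euclidean distance from
the reference centroid in the first three PCs (10-SD rule), and
relatedness pruning from a standardized-genotype kinship estimator
(first/second-degree cutoff 0.0884).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_genotypes import MISSING


@dataclass
class PCResult:
    scores: np.ndarray          # n_samples x k
    explained_var: np.ndarray   # fraction of total variance per component

    def __post_init__(self) -> None:
        ev = self.explained_var
        assert np.all(ev >= 0) and np.all(np.diff(ev) <= 1e-12) and ev.sum() <= 1 + 1e-9


def standardize_genotypes(G: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Center and scale dosages: (g - 2q) / sqrt(2 q (1-q)) with q the
    coded-allele frequency; missing calls are imputed to the mean (0 after
    centering).  Monomorphic SNPs must be filtered beforehand."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0.0) | (freqs >= 1.0)):
        raise ValueError("monomorphic SNP in standardization; run SNP QC first")
    X = np.where(G == MISSING, 2.0 * freqs[None, :], G.astype(float))
    return (X - 2.0 * freqs[None, :]) / np.sqrt(2.0 * freqs * (1.0 - freqs))[None, :]


def compute_pcs(X: np.ndarray, k: int = 10) -> PCResult:
    """Top-k principal components of the (already standardized) matrix.

    Equivalent to the SVD of the column-centered data (scores = U_k s_k,
    explained-variance fractions = squared-singular-value shares), but
    computed through the eigendecomposition of the smaller Gram matrix,
    which is much faster when one dimension dominates.
    """
    n, m = X.shape
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds the rank bound min(n-1, m)={min(n - 1, m)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    if m <= n:
        w, V = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(w)[::-1][:k]
        scores = Xc @ V[:, order]
    else:
        w, U = np.linalg.eigh(Xc @ Xc.T)
        order = np.argsort(w)[::-1][:k]
        scores = U[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    lam = np.clip(w[order], 0.0, None)
    total = float(np.clip(w, 0.0, None).sum())
    return PCResult(scores=scores, explained_var=lam / total)


def outlier_distance(scores: np.ndarray, explained_var: np.ndarray,
                     reference_mask: np.ndarray, *, n_pcs: int = 3,
                     sd_threshold: float = 10.0,
                     reference_labels: np.ndarray | None = None) -> pd.DataFrame:
    """Explained-variance-weighted distance from the reference centroid.

    d_i = sqrt( sum_{j<=n_pcs} v_j (s_ij - c_j)^2 ) with v_j the explained
    -variance fraction of PC j and c the centroid of the reference
    samples; the SD of d over the reference samples sets the exclusion
    scale (excluded iff d > sd_threshold * SD).  With
    ``reference_labels`` the centroid/SD are computed per reference
    subgroup and a sample is excluded only if it is an outlier with
    respect to every subgroup.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.sum() < 2:
        raise ValueError("need at least two reference samples")
    if scores.shape[1] < n_pcs:
        raise ValueError(f"need {n_pcs} PCs, got {scores.shape[1]}")
    S = scores[:, :n_pcs]
    v = np.asarray(explained_var[:n_pcs], dtype=float)

    def _one(ref_rows: np.ndarray):
        centroid = S[ref_rows].mean(axis=0)
        d = np.sqrt(((S - centroid) ** 2 * v).sum(axis=1))
        sd = d[ref_rows].std(ddof=1)
        return d, centroid, sd

    if reference_labels is None:
        d, centroid, sd = _one(reference_mask)
        excluded = d > sd_threshold * sd
        return pd.DataFrame({"distance": d, "sd_units": d / sd,
                             "excluded": excluded})
    labels = np.asarray(reference_labels, dtype=object)
    per_group = []
    for lab in pd.unique(labels[reference_mask]):
        d, _, sd = _one(reference_mask & (labels == lab))
        per_group.append(d / sd)
    sd_units = np.min(np.stack(per_group, axis=1), axis=1)
    return pd.DataFrame({"distance": np.nan, "sd_units": sd_units,
                         "excluded": sd_units > sd_threshold})


def estimate_kinship(G: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Pairwise kinship from standardized genotypes.

    phi_ij = (1 / 2 M_ij) sum_m (g_im - 2 q_m)(g_jm - 2 q_m) / (2 q_m (1 - q_m))
    over the M_ij loci non-missing in both individuals.  Self-kinship of
    an outbred individual and of a duplicated pair is ~0.5;
    parent-offspring ~0.25; second-degree ~0.125.
    """
    if G.shape[0] < 2:
        raise ValueError("kinship needs at least two individuals")
    X = standardize_genotypes(G, freqs)
    X = np.where(G == MISSING, 0.0, X)
    obs = (G != MISSING).astype(float)
    shared = obs @ obs.T
    if np.any(shared == 0):
        raise ValueError("some pair shares no genotyped locus")
    return (X @ X.T) / (2.0 * shared)


def exclude_relatives(kinship: np.ndarray, ids: list,
                      threshold: float = 0.0884) -> list:
    """Greedy relatedness pruning.

    While any off-diagonal kinship exceeds the threshold, drop the sample
    with the most over-threshold partners; ties are broken by dropping the
    lexicographically larger id (earlier ids are retained).  The default
    threshold is the conventional second-degree kinship boundary
    (2^(-7/2) ~ 0.0884), so first- and second-degree relatives are pruned.
    Returns the retained ids in input order.
    """
    n = len(ids)
    if kinship.shape != (n, n):
        raise ValueError("kinship matrix does not match id list")
    adj = np.asarray(kinship) > threshold
    np.fill_diagonal(adj, False)
    adj = adj | adj.T
    active = np.ones(n, dtype=bool)
    while True:
        deg = (adj & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max(initial=0) == 0:
            break
        worst = np.nonzero(deg == deg.max())[0]
        drop = max(worst, key=lambda i: str(ids[i]))
        active[drop] = False
    return [ids[i] for i in range(n) if active[i]]
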