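"""Two-track meta-analysis of per-cohort Cox estimates.

Significance: Stouffer's weighted Z over per-cohort two-sided z-scores,
weights = number of deaths (Z = sum w z / sqrt(sum w^2)).  Rescaling a
cohort's heterozygosity covariate (e.g. a different SNP-panel size)
changes its beta but not its z, so the combined Z is array-size
invariant.

Effect size: per-cohort log-HRs on the raw heterozygosity statistic t
are standardized by the cohort SD of t (beta_std = beta x SD(t), se_std
= se x SD(t)) and pooled by fixed-effect inverse-variance weighting.
This only partially removes the panel-size bias, but yields an
interpretable per-SD effect; the combined hazard ratio per SD is
exp(beta_std), reported also as a percent risk change per SD.

Heterogeneity: Cochran's Q with I^2; subgroup comparison pools each
group by IVW and applies the between-group Q test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CohortEstimate:
    """One cohort's Cox output for heterozygosity."""

    cohort: str
    beta: float            # log-HR per unit t (raw metric scale)
    se: float
    n_deaths: int
    n_individuals: int
    sd_het: float          # cohort SD of t
    ancestry: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if self.n_deaths > self.n_individuals:
            raise ValueError("more deaths than individuals")

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def beta_std(self) -> float:
        return self.beta * self.sd_het

    @property
    def se_std(self) -> float:
        return self.se * self.sd_het


def standardize_estimate(beta: float, se: float, sd_het: float) -> tuple[float, float]:
    """Scale a per-unit-t estimate to the per-SD scale; z is unchanged."""
    if sd_het <= 0:
        raise ValueError("sd_het must be positive")
    return beta * sd_het, se * sd_het


def stouffer_combine(z: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted Stouffer combination: Z = sum w z / sqrt(sum w^2), with a
    two-sided normal p.  Weights are death counts by convention here
    (sqrt-death weighting is the caller's choice of ``weights``)."""
    z = np.asarray(z, dtype=float)
    w = np.asarray(weights, dtype=float)
    if z.size == 0:
        raise ValueError("need at least one cohort")
    if np.any(w <= 0) or not np.any(w > 0):
        raise ValueError("weights must be positive")
    Z = float((w * z).sum() / np.sqrt((w ** 2).sum()))
    return Z, float(2.0 * stats.norm.sf(abs(Z)))


def ivw_combine(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance pooling.

    weights 1/se^2; combined beta = sum(w b)/sum(w), combined
    se = 1/sqrt(sum w); two-sided normal p on the combined z.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("need at least one estimate")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s ** 2
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def cochran_q(betas: np.ndarray, ses: np.ndarray) -> tuple[float, int, float, float]:
    """Cochran's Q heterogeneity test and I^2.

    Q = sum w_k (b_k - b_pooled)^2, df = K-1, p from chi-square;
    I^2 = max(0, (Q - df)/Q) x 100.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("heterogeneity needs at least two estimates")
    w = 1.0 / s ** 2
    pooled = (w * b).sum() / w.sum()
    Q = float((w * (b - pooled) ** 2).sum())
    df = b.size - 1
    p = float(stats.chi2.sf(Q, df))
    i2 = float(max(0.0, (Q - df) / Q) * 100.0) if Q > 0 else 0.0
    return Q, df, p, i2


def subgroup_compare(groups: dict[str, list[CohortEstimate]]) -> tuple[float, int, float]:
    """Between-group heterogeneity: pool each group by IVW on the
    standardized scale, then apply Q across the group-level estimates
    (df = #groups - 1; for two groups this is the squared z-difference
    test)."""
    if len(groups) < 2:
        raise ValueError("need at least two subgroups")
    gb, gs = [], []
    for name, ests in groups.items():
        if not ests:
            raise ValueError(f"subgroup {name!r} has no estimates")
        beta, se, _ = ivw_combine([e.beta_std for e in ests],
                                  [e.se_std for e in ests])
        gb.append(beta)
        gs.append(se)
    w = 1.0 / np.asarray(gs) ** 2
    b = np.asarray(gb)
    pooled = (w * b).sum() / w.sum()
    Q = float((w * (b - pooled) ** 2).sum())
    df = len(groups) - 1
    return Q, df, float(stats.chi2.sf(Q, df))


def risk_change_per_sd(beta_std: float) -> float:
    """Percent risk change per +1 SD of heterozygosity:
    (1 - exp(beta_std)) x 100; positive means decreased risk."""
    return (1.0 - np.exp(beta_std)) * 100.0


def meta_analyze(estimates: list[CohortEstimate], scope: str = "overall",
                 stouffer_weight: str = "deaths") -> dict:
    """Full two-track combination of one set of cohort estimates."""
    if not estimates:
        raise ValueError("no estimates to combine")
    z = np.array([e.z for e in estimates])
    deaths = np.array([e.n_deaths for e in estimates], dtype=float)
    w = np.sqrt(deaths) if stouffer_weight == "sqrt_deaths" else deaths
    Z, p_stouffer = stouffer_combine(z, w)
    bs = np.array([e.beta_std for e in estimates])
    ss = np.array([e.se_std for e in estimates])
    beta, se, p_ivw = ivw_combine(bs, ss)
    if len(estimates) >= 2:
        Q, df, p_q, i2 = cochran_q(bs, ss)
    else:
        Q, df, p_q, i2 = 0.0, 0, float("nan"), 0.0
    hr = float(np.exp(beta))
    return {
        "scope": scope, "k": len(estimates),
        "n_individuals": int(sum(e.n_individuals for e in estimates)),
        "n_deaths": int(deaths.sum()),
        "beta_std": beta, "se_std": se, "hr_per_sd": hr,
        "risk_change_pct_per_sd": risk_change_per_sd(beta),
        "stouffer_z": Z, "stouffer_p": p_stouffer, "ivw_p": p_ivw,
        "cochran_q": Q, "q_df": df, "q_p": p_q, "i2_pct": i2,
    }


def meta_table(groups: dict[str, list[CohortEstimate]],
               stouffer_weight: str = "deaths") -> pd.DataFrame:
    """Forest-plot table: one row per subgroup plus a between-group test
    row when there are >= 2 groups (the tabular form of the study's
    forest figures)."""
    rows = [meta_analyze(ests, scope=name, stouffer_weight=stouffer_weight)
            for name, ests in groups.items()]
    df = pd.DataFrame(rows)
    if len(groups) >= 2:
        Q, dfree, p = subgroup_compare(groups)
        df.attrs["between_group_q"] = Q
        df.attrs["between_group_df"] = dfree
        df.attrs["between_group_p"] = p
    return df


def cohort_table(estimates: list[CohortEstimate]) -> pd.DataFrame:
    """Per-cohort forest rows: standardized estimate, CI, z, and both
    weighting columns (IVW weight share and death count)."""
    w = np.array([1.0 / e.se_std ** 2 for e in estimates])
    return pd.DataFrame({
        "cohort": [e.cohort for e in estimates],
        "ancestry": [e.ancestry for e in estimates],
        "beta_std": [e.beta_std for e in estimates],
        "se_std": [e.se_std for e in estimates],
        "hr_per_sd": [float(np.exp(e.beta_std)) for e in estimates],
        "z": [e.z for e in estimates],
        "n_deaths": [e.n_deaths for e in estimates],
        "n_individuals": [e.n_individuals for e in estimates],
        "ivw_weight_pct": 100.0 * w / w.sum(),
    })


def forest_plot(table: pd.DataFrame, path, title: str = "") -> None:
    """Forest plot of a meta table (one row per scope): standardized
    log-HR with 95% CI, diamond-free minimal rendering."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.arange(len(table))[::-1]
    b = table["beta_std"].to_numpy()
    s = table["se_std"].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(table) + 1.5))
    ax.errorbar(b, y, xerr=1.96 * s, fmt="s", color="k", capsize=3)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(table["scope"])
    ax.set_xlabel("standardized log hazard ratio per SD of heterozygosity")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def estimates_from_records(records: list[dict]) -> list[CohortEstimate]:
    """Rebuild CohortEstimate objects from fit-JSON dicts."""
    return [CohortEstimate(
        cohort=r["cohort"], beta=r["beta"], se=r["se"],
        n_deaths=r["events"], n_individuals=r["n"], sd_het=r["sd_het"],
        ancestry=r.get("ancestry", "")) for r in records]
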