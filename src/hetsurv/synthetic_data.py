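"""Synthetic multi-cohort genotype + survival data with known ground truth.

The generator emulates the structure of a prospective multi-cohort
heterozygosity–fitness study: per-cohort SNP panels (different sizes,
mimicking different genotyping arrays), Hardy–Weinberg genotypes with
per-individual inbreeding coefficients f_i (the source of real
heterozygosity variance, standing in for variable genomic autozygosity),
two synthetic ancestral reference populations with diverged allele
frequencies, survival times whose hazard depends on standardized
heterozygosity, left truncation at study entry, administrative censoring,
and competing causes of death.

Genotype law given minor-allele frequency q and inbreeding f:
    P(hom major) = p^2 + p q f,   P(het) = 2 p q (1 - f),
    P(hom minor) = q^2 + p q f,   with p = 1 - q.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  # genotype code for a missing call

PHENOTYPE_COLUMNS = [
    "iid", "entry_age", "exit_age", "dead", "cause", "sex", "bmi",
    "education", "income", "center", "ancestry", "cohort",
]

EDUCATION_LEVELS = ["1", "2", "3", "4", "Missing"]
CAUSES = ["cancer", "cvd", "other"]


class InvalidConfigError(ValueError):
    """Raised when a simulation parameter is outside its valid domain."""


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    ``n_individuals`` and ``n_snps`` may be a single int (all cohorts
    equal) or one value per cohort (emulating different arrays).
    ``ancestry_mix`` gives the proportion of cohorts drawn from each
    synthetic reference population; each cohort is ancestry-homogeneous,
    mirroring per-ancestry association analyses.
    """

    n_cohorts: int = 4
    n_individuals: int | Sequence[int] = 2000
    n_snps: int | Sequence[int] = 5000
    n_chromosomes: int = 22
    allele_freq_range: tuple[float, float] = (0.15, 0.5)
    inbreeding_mean: float = 0.02
    inbreeding_sd: float = 0.02
    true_log_hr_per_sd: float = math.log(0.98)
    cause_log_hr: dict = field(default_factory=dict)  # optional per-cause extra effect
    baseline_hazard_rate: float = 0.012  # per year
    weibull_shape: float = 1.0  # 1.0 = exponential baseline
    entry_age_range: tuple[float, float] = (50.0, 70.0)
    admin_censor_age: float = 95.0
    ancestry_mix: dict = field(default_factory=lambda: {"EUR": 0.75, "AFR": 0.25})
    fst: float = 0.05  # Balding-Nichols divergence between reference populations
    cause_mix: dict = field(default_factory=lambda: {"cancer": 0.35, "cvd": 0.35, "other": 0.30})
    missing_rate: float = 0.002
    n_reference_per_pop: int = 100
    sex_log_hr: float = 0.4
    bmi_log_hr_per_unit: float = 0.02

    def validate(self) -> None:
        if self.n_cohorts < 1:
            raise InvalidConfigError("n_cohorts must be >= 1")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("allele_freq_range must lie within (0, 0.5]")
        for name, mix in (("ancestry_mix", self.ancestry_mix), ("cause_mix", self.cause_mix)):
            vals = np.asarray(list(mix.values()), dtype=float)
            if len(vals) == 0 or np.any(vals < 0) or not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
                raise InvalidConfigError(f"{name} proportions must be >= 0 and sum to 1")
        if len(self.ancestry_mix) < 2:
            raise InvalidConfigError("ancestry_mix needs >= 2 reference populations")
        if not (0.0 <= self.missing_rate < 1.0):
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        if self.baseline_hazard_rate <= 0:
            raise InvalidConfigError("baseline_hazard_rate must be positive")
        if not (self.entry_age_range[0] < self.entry_age_range[1] < self.admin_censor_age):
            raise InvalidConfigError("entry ages must be increasing and below admin_censor_age")
        for m in np.atleast_1d(self.per_cohort("n_snps")):
            if m < 1:
                raise InvalidConfigError("n_snps must be >= 1")
        if not (0.0 <= self.inbreeding_mean < 1.0) or self.inbreeding_sd < 0:
            raise InvalidConfigError("inbreeding parameters outside [0,1) / sd >= 0")

    def per_cohort(self, attr: str) -> np.ndarray:
        """Expand a scalar-or-sequence field to one value per cohort."""
        val = getattr(self, attr)
        if np.isscalar(val):
            return np.full(self.n_cohorts, val, dtype=int)
        arr = np.asarray(val, dtype=int)
        if arr.shape != (self.n_cohorts,):
            raise InvalidConfigError(f"{attr} must be scalar or length n_cohorts")
        return arr

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
            elif isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("allele_freq_range", "entry_age_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """What the generator actually used, for recovery checks."""

    f: np.ndarray                      # per-individual inbreeding coefficient
    het_z: np.ndarray                  # standardized heterozygosity used in the hazard
    t_true: np.ndarray                 # raw heterozygosity statistic at true frequencies
    true_log_hr_per_sd: float
    allele_freqs: np.ndarray           # per-SNP generating minor-allele frequency

    def to_dict(self) -> dict:
        return {
            "f": self.f.tolist(),
            "het_z": self.het_z.tolist(),
            "t_true": self.t_true.tolist(),
            "true_log_hr_per_sd": self.true_log_hr_per_sd,
            "allele_freqs": self.allele_freqs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            f=np.asarray(d["f"]),
            het_z=np.asarray(d["het_z"]),
            t_true=np.asarray(d["t_true"]),
            true_log_hr_per_sd=float(d["true_log_hr_per_sd"]),
            allele_freqs=np.asarray(d["allele_freqs"]),
        )


@dataclass
class Cohort:
    """One simulated cohort: study + reference genotypes and phenotypes."""

    name: str
    ancestry: str
    genotypes: np.ndarray          # (n_study + n_reference) x M, int8, MISSING = -1
    sample_ids: list
    groups: pd.DataFrame           # iid, group in {study, reference:<pop>}
    snp_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    phenotypes: pd.DataFrame       # study individuals only
    truth: GroundTruth

    @property
    def study_mask(self) -> np.ndarray:
        return (self.groups["group"] == "study").to_numpy()


# ---------------------------------------------------------------------------
# elementary generators


def simulate_allele_frequencies(n_snps: int, freq_range: tuple[float, float],
                                rng: np.random.Generator) -> np.ndarray:
    """Minor-allele frequencies drawn uniformly within ``freq_range``."""
    lo, hi = freq_range
    if n_snps < 1:
        raise InvalidConfigError("n_snps must be >= 1")
    if not (0.0 < lo <= hi <= 0.5):
        raise InvalidConfigError("freq_range must lie within (0, 0.5]")
    return rng.uniform(lo, hi, size=n_snps)


def diverge_frequencies(freqs: np.ndarray, fst: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols draw of a daughter population's frequencies.

    p' ~ Beta(p (1-F)/F, (1-p)(1-F)/F); expectation p, variance F p (1-p).
    """
    if not (0.0 < fst < 1.0):
        raise InvalidConfigError("fst must be in (0, 1)")
    a = freqs * (1.0 - fst) / fst
    b = (1.0 - freqs) * (1.0 - fst) / fst
    out = rng.beta(a, b)
    return np.clip(out, 1e-4, 1.0 - 1e-4)


def simulate_inbreeding(n: int, mean: float, sd: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-individual inbreeding f_i, normal(mean, sd) truncated to [0, 1)."""
    if sd == 0:
        return np.full(n, mean)
    f = rng.normal(mean, sd, size=n)
    # resample the (typically few) out-of-range draws rather than clipping,
    # so the mean is not dragged by a point mass at 0
    bad = (f < 0) | (f >= 1)
    while bad.any():
        f[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (f < 0) | (f >= 1)
    return f


def simulate_genotypes(freqs: np.ndarray, f: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw an n x M genotype matrix (minor-allele counts) under the
    inbreeding-adjusted Hardy–Weinberg law.

    freqs are per-SNP minor-allele frequencies in (0,1); f is the
    per-individual inbreeding coefficient in [0,1).  Loci are independent
    given f_i.
    """
    freqs = np.asarray(freqs, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f >= 1)):
        raise InvalidConfigError("inbreeding coefficients must lie in [0, 1)")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise InvalidConfigError("allele frequencies must lie in (0, 1)")
    q = freqs[None, :]
    p = 1.0 - q
    fi = f[:, None]
    p_hom_minor = q * q + p * q * fi
    p_het = 2.0 * p * q * (1.0 - fi)
    u = rng.random((f.shape[0], freqs.shape[0]))
    g = np.zeros(u.shape, dtype=np.int8)
    g[u < p_hom_minor] = 2
    g[(u >= p_hom_minor) & (u < p_hom_minor + p_het)] = 1
    return g


def inject_missingness(G: np.ndarray, rate: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Set genotypes missing completely at random at the given rate."""
    if not (0.0 <= rate < 1.0):
        raise InvalidConfigError("missing rate must be in [0, 1)")
    if rate == 0.0:
        return G
    out = G.copy()
    out[rng.random(G.shape) < rate] = MISSING
    return out


def true_het_scores(G: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Heterozygosity statistic t at the generating frequencies.

    t = (number of heterozygous loci) / sum_m 2 p_m (1 - p_m); symmetric in
    p vs 1-p, so minor/major orientation is immaterial.
    """
    expected = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    return (G == 1).sum(axis=1) / expected


def simulate_survival(het_z: np.ndarray, covariate_lp: np.ndarray,
                      true_log_hr_per_sd: float, baseline_rate: float,
                      entry_ages: np.ndarray, censor_age: float,
                      rng: np.random.Generator, *,
                      weibull_shape: float = 1.0,
                      cause_mix: dict | None = None,
                      cause_log_hr: dict | None = None) -> pd.DataFrame:
    """Left-truncated survival outcomes under a proportional-hazards law.

    The all-cause hazard at age a is
        lambda(a) = k lam^k a^(k-1) * exp(beta het_z + covariate_lp)
    split across causes proportionally to ``cause_mix`` (each cause may
    carry an extra per-SD log-HR via ``cause_log_hr``).  Death ages are
    drawn by inverting the cumulative hazard conditional on survival to
    the entry age, so the output has exactly the entry/exit/status
    structure of a prospective cohort; exits past ``censor_age`` are
    administratively censored alive.
    """
    if baseline_rate <= 0:
        raise InvalidConfigError("baseline hazard rate must be positive")
    entry_ages = np.asarray(entry_ages, dtype=float)
    if np.any(entry_ages >= censor_age):
        raise InvalidConfigError("all entry ages must precede the censoring age")
    n = het_z.shape[0]
    cause_mix = cause_mix or {"cancer": 0.35, "cvd": 0.35, "other": 0.30}
    cause_log_hr = cause_log_hr or {}
    k = weibull_shape
    causes = list(cause_mix)
    # competing cause-specific hazards; min over causes is the death age
    death_age = np.full(n, np.inf)
    death_cause = np.array(["none"] * n, dtype=object)
    base_lp = covariate_lp + true_log_hr_per_sd * het_z
    for c in causes:
        share = cause_mix[c]
        if share <= 0:
            continue
        lp_c = base_lp + cause_log_hr.get(c, 0.0) * het_z
        # H_c(t) = share * (lam t)^k exp(lp_c); solve H_c(T)=H_c(a)+E
        e = rng.exponential(size=n)
        scale = share * baseline_rate ** k * np.exp(lp_c)
        t_c = (entry_ages ** k + e / scale) ** (1.0 / k)
        sooner = t_c < death_age
        death_age[sooner] = t_c[sooner]
        death_cause[sooner] = c
    dead = death_age <= censor_age
    exit_age = np.where(dead, death_age, censor_age)
    # guard exact ties with entry (probability zero in theory)
    exit_age = np.maximum(exit_age, entry_ages + 1.0 / 365.25 / 24.0)
    return pd.DataFrame({
        "entry_age": entry_ages,
        "exit_age": exit_age,
        "dead": dead.astype(int),
        "cause": np.where(dead, death_cause, "NA"),
    })


# ---------------------------------------------------------------------------
# cohort assembly


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    sex = rng.choice(["M", "F"], size=n)
    bmi = np.clip(rng.normal(27.0, 4.5, size=n), 16.0, 50.0)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=[0.25, 0.35, 0.25, 0.10, 0.05])
    income = rng.choice(["1", "2", "3"], size=n, p=[0.3, 0.4, 0.3])
    center = rng.choice(["1", "2"], size=n)
    return pd.DataFrame({"sex": sex, "bmi": bmi, "education": education,
                         "income": income, "center": center})


_EDU_LOG_HR = {"1": 0.10, "2": 0.0, "3": -0.05, "4": -0.10, "Missing": 0.0}


def _cohort_ancestries(config: SimConfig) -> list[str]:
    """Assign each cohort to a reference population per ancestry_mix."""
    pops = list(config.ancestry_mix)
    weights = np.asarray([config.ancestry_mix[p] for p in pops])
    counts = np.floor(weights * config.n_cohorts).astype(int)
    # distribute the remainder to the largest fractional parts
    rem = config.n_cohorts - counts.sum()
    order = np.argsort(-(weights * config.n_cohorts - counts))
    for j in range(rem):
        counts[order[j % len(pops)]] += 1
    out: list[str] = []
    for pop, c in zip(pops, counts):
        out.extend([pop] * c)
    return out[: config.n_cohorts]


def simulate_cohort(config: SimConfig, cohort_index: int,
                    seed_seq: np.random.SeedSequence) -> Cohort:
    """Simulate one cohort (study samples, reference panel, phenotypes)."""
    config.validate()
    rng = np.random.default_rng(seed_seq)
    n = int(config.per_cohort("n_individuals")[cohort_index])
    m = int(config.per_cohort("n_snps")[cohort_index])
    ancestries = _cohort_ancestries(config)
    ancestry = ancestries[cohort_index]
    pops = list(config.ancestry_mix)

    base = simulate_allele_frequencies(m, config.allele_freq_range, rng)
    pop_freqs = {pops[0]: base}
    for pop in pops[1:]:
        pop_freqs[pop] = diverge_frequencies(base, config.fst, rng)

    f = simulate_inbreeding(n, config.inbreeding_mean, config.inbreeding_sd, rng)
    study = simulate_genotypes(pop_freqs[ancestry], f, rng)
    t_true = true_het_scores(study, pop_freqs[ancestry])
    sd_t = t_true.std(ddof=1)
    het_z = (t_true - t_true.mean()) / sd_t

    covs = _simulate_covariates(n, rng)
    lp = (config.sex_log_hr * (covs["sex"] == "M").to_numpy()
          + config.bmi_log_hr_per_unit * (covs["bmi"].to_numpy() - 27.0)
          + covs["education"].map(_EDU_LOG_HR).to_numpy())
    entry = rng.uniform(*config.entry_age_range, size=n)
    surv = simulate_survival(
        het_z, lp, config.true_log_hr_per_sd, config.baseline_hazard_rate,
        entry, config.admin_censor_age, rng,
        weibull_shape=config.weibull_shape,
        cause_mix=config.cause_mix, cause_log_hr=config.cause_log_hr,
    )

    study = inject_missingness(study, config.missing_rate, rng)

    # reference panel: f = 0 individuals from every population
    ref_blocks, ref_ids, ref_groups = [], [], []
    for pop in pops:
        gref = simulate_genotypes(pop_freqs[pop],
                                  np.zeros(config.n_reference_per_pop), rng)
        ref_blocks.append(gref)
        ref_ids.extend(f"ref_{pop}_{j}" for j in range(config.n_reference_per_pop))
        ref_groups.extend([f"reference:{pop}"] * config.n_reference_per_pop)

    name = f"cohort{cohort_index + 1:02d}"
    study_ids = [f"{name}_ind{j:05d}" for j in range(n)]
    sample_ids = study_ids + ref_ids
    genotypes = np.vstack([study] + ref_blocks)
    groups = pd.DataFrame({"iid": sample_ids,
                           "group": ["study"] * n + ref_groups})

    snps_per_chrom = np.array_split(np.arange(m), config.n_chromosomes)
    chrom = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=int)
    for ci, idx in enumerate(snps_per_chrom, start=1):
        chrom[idx] = ci
        pos[idx] = 10_000 * (np.arange(len(idx)) + 1)
    snp_ids = [f"snp{j + 1:06d}" for j in range(m)]

    pheno = pd.concat([pd.DataFrame({"iid": study_ids}), surv, covs], axis=1)
    pheno["ancestry"] = ancestry
    pheno["cohort"] = name
    pheno = pheno[PHENOTYPE_COLUMNS]

    truth = GroundTruth(f=f, het_z=het_z, t_true=t_true,
                        true_log_hr_per_sd=config.true_log_hr_per_sd,
                        allele_freqs=pop_freqs[ancestry])
    return Cohort(name=name, ancestry=ancestry, genotypes=genotypes,
                  sample_ids=sample_ids, groups=groups, snp_ids=snp_ids,
                  chrom=chrom, pos=pos, phenotypes=pheno, truth=truth)


def simulate_study(config: SimConfig, seed: int) -> list[Cohort]:
    """Simulate all cohorts; per-cohort seeds are spawned deterministically."""
    config.validate()
    children = np.random.SeedSequence(seed).spawn(config.n_cohorts)
    return [simulate_cohort(config, i, children[i]) for i in range(config.n_cohorts)]


# ---------------------------------------------------------------------------
# on-disk representation

FORMATS = ("tsv", "vcf", "plink")


def write_cohort(cohort: Cohort, outdir: str | pathlib.Path,
                 fmt: str = "tsv") -> pathlib.Path:
    """Write one cohort to ``outdir``: genotypes (tsv/vcf/plink), phenotype
    TSV, sample-group TSV and ground-truth JSON."""
    from . import io_genotypes  # local import to avoid a cycle

    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: {', '.join(FORMATS)}")
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"tsv": "tsv", "vcf": "vcf", "plink": "bed"}[fmt]
    io_genotypes.write_genotypes(
        outdir / f"genotypes.{ext}", fmt, cohort.genotypes, cohort.sample_ids,
        cohort.snp_ids, cohort.chrom, cohort.pos)
    cohort.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    cohort.groups.to_csv(outdir / "groups.tsv", sep="\t", index=False)
    meta = {"name": cohort.name, "ancestry": cohort.ancestry, "format": fmt}
    (outdir / "cohort.json").write_text(json.dumps(meta, indent=1))
    (outdir / "truth.json").write_text(json.dumps(cohort.truth.to_dict()))
    return outdir


def read_cohort(indir: str | pathlib.Path) -> Cohort:
    """Inverse of :func:`write_cohort`."""
    from . import io_genotypes

    indir = pathlib.Path(indir)
    meta = json.loads((indir / "cohort.json").read_text())
    fmt = meta["format"]
    path = indir / ("genotypes.tsv" if fmt == "tsv"
                    else "genotypes.vcf" if fmt == "vcf" else "genotypes.bed")
    G, sample_ids, snp_ids, chrom, pos = io_genotypes.read_genotypes(path, fmt)
    pheno = pd.read_csv(indir / "phenotypes.tsv", sep="\t", keep_default_na=False,
                        dtype={"education": str, "income": str, "center": str})
    groups = pd.read_csv(indir / "groups.tsv", sep="\t")
    truth = GroundTruth.from_dict(json.loads((indir / "truth.json").read_text()))
    return Cohort(name=meta["name"], ancestry=meta["ancestry"], genotypes=G,
                  sample_ids=sample_ids, groups=groups, snp_ids=snp_ids,
                  chrom=chrom, pos=pos, phenotypes=pheno, truth=truth)
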