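"""Config-driven orchestration of the full heterozygosity–survival study.

simulate (or ingest) cohorts → SNP QC → sample QC (PCA, outliers,
relatedness) → heterozygosity scores (genome-wide and per chromosome) →
per-cohort Cox fits (all-cause, per-cause, per-sex, per-chromosome) →
meta-analyses (overall, ancestry, chromosome, cause, sex).

Everything is computed strictly within cohort (frequencies, QC,
standardization); only z-scores and standardized betas cross cohort
boundaries, inside the meta stage.  One master seed drives per-stage
child seeds, so a run is deterministic end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import genotype_qc, heterozygosity, meta, sample_qc, survival
from .synthetic_data import Cohort, SimConfig, read_cohort, simulate_study, write_cohort

ANALYSES = ("overall", "ancestry", "chromosome", "cause", "sex")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class StudyConfig:
    """Study-level options around the simulation config."""

    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    analyses: tuple = ANALYSES
    qc: genotype_qc.QCThresholds = field(default_factory=genotype_qc.QCThresholds)
    n_pcs: int = 10
    sd_threshold: float = 10.0
    kinship_threshold: float = 0.0884
    include_pcs: bool = True
    do_sample_qc: bool = True
    stouffer_weight: str = "deaths"
    write_cohorts: bool = False
    cohort_format: str = "tsv"

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "StudyConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        sim = SimConfig.from_dict(raw.pop("sim", {}))
        qc = genotype_qc.QCThresholds(**raw.pop("qc", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown study config keys: {sorted(unknown)}")
        cfg = cls(sim=sim, qc=qc, **raw)
        if isinstance(cfg.analyses, list):
            cfg.analyses = tuple(cfg.analyses)
        bad = set(cfg.analyses) - set(ANALYSES)
        if bad:
            raise ValueError(f"unknown analyses: {sorted(bad)}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps({
            "sim": self.sim.to_dict(), "seed": self.seed,
            "analyses": list(self.analyses),
            "qc": dataclasses.asdict(self.qc), "n_pcs": self.n_pcs,
            "sd_threshold": self.sd_threshold,
            "kinship_threshold": self.kinship_threshold,
            "include_pcs": self.include_pcs, "do_sample_qc": self.do_sample_qc,
            "stouffer_weight": self.stouffer_weight,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-cohort stages


def snp_qc_cohort(cohort: Cohort, thresholds: genotype_qc.QCThresholds):
    """SNP QC on the cohort's study samples.  Returns (keep_mask, panel,
    exclusion_report); frequencies and HWE are study-sample statistics."""
    study = cohort.genotypes[cohort.study_mask]
    panel = genotype_qc.build_panel(study, cohort.snp_ids, cohort.chrom, cohort.pos)
    _, panel_f, report = genotype_qc.filter_snps(study, panel, thresholds)
    keep = np.isin(np.asarray(cohort.snp_ids), panel_f["snp_id"].to_numpy())
    return keep, panel_f, report


def sample_qc_cohort(cohort: Cohort, keep_snps: np.ndarray, *,
                     n_pcs: int = 10, sd_threshold: float = 10.0,
                     kinship_threshold: float = 0.0884) -> dict:
    """PCA on the combined study+reference matrix, outlier exclusion
    against the cohort-ancestry reference cluster, and relatedness
    pruning among study samples."""
    G = cohort.genotypes[:, keep_snps]
    study_mask = cohort.study_mask
    freqs = genotype_qc.allele_frequencies(G[study_mask])["coded_freq"].to_numpy()
    X = sample_qc.standardize_genotypes(G, freqs)
    k = min(n_pcs, min(G.shape[0] - 1, G.shape[1]))
    pcs = sample_qc.compute_pcs(X, k=k)
    ref_mask = (cohort.groups["group"] == f"reference:{cohort.ancestry}").to_numpy()
    outliers = sample_qc.outlier_distance(
        pcs.scores, pcs.explained_var, ref_mask, sd_threshold=sd_threshold)
    outliers.insert(0, "iid", cohort.sample_ids)

    study_ids = [sid for sid, m in zip(cohort.sample_ids, study_mask) if m]
    ok_outlier = ~outliers["excluded"].to_numpy() & study_mask
    keep_ids = [sid for sid, m in zip(cohort.sample_ids, ok_outlier) if m]
    idx = np.nonzero(ok_outlier)[0]
    kin = sample_qc.estimate_kinship(cohort.genotypes[np.ix_(idx, keep_snps)], freqs)
    retained = sample_qc.exclude_relatives(kin, keep_ids, threshold=kinship_threshold)

    iu = np.triu_indices_from(kin, k=1)
    over = kin[iu] > kinship_threshold
    kin_pairs = pd.DataFrame({
        "iid1": [keep_ids[i] for i in iu[0][over]],
        "iid2": [keep_ids[j] for j in iu[1][over]],
        "kinship": kin[iu][over],
    })
    pc_frame = pd.DataFrame(pcs.scores, columns=[f"pc{j+1}" for j in range(k)])
    pc_frame.insert(0, "iid", cohort.sample_ids)
    return {"pcs": pc_frame, "explained_var": pcs.explained_var,
            "outliers": outliers, "kinship_pairs": kin_pairs,
            "retained_ids": retained,
            "n_excluded_outlier": int((study_mask & outliers["excluded"]).sum()),
            "n_excluded_related": len(keep_ids) - len(retained)}


def het_cohort(cohort: Cohort, keep_snps: np.ndarray,
               retained_ids: list) -> pd.DataFrame:
    """Genome-wide and per-chromosome heterozygosity for retained study
    samples, standardized within cohort."""
    id_index = {sid: i for i, sid in enumerate(cohort.sample_ids)}
    rows = np.array([id_index[s] for s in retained_ids])
    G = cohort.genotypes[np.ix_(rows, np.nonzero(keep_snps)[0])]
    study_rows = cohort.genotypes[cohort.study_mask][:, keep_snps]
    p_major = genotype_qc.allele_frequencies(study_rows)["p_major"].to_numpy()
    chrom = cohort.chrom[keep_snps]

    genome = heterozygosity.het_scores(G, p_major, iids=retained_ids)
    by_chrom = heterozygosity.het_scores_by_chromosome(G, chrom, p_major,
                                                       iids=retained_ids)
    out = pd.concat([genome, by_chrom], ignore_index=True)
    zs = []
    for scope, sub in out.groupby("scope", sort=False):
        std = heterozygosity.standardize_scores(sub["t"].to_numpy())
        sub = sub.copy()
        sub["z"] = std["z"].to_numpy()
        sub["cohort_sd_t"] = std["cohort_sd"].iloc[0]
        zs.append(sub)
    return pd.concat(zs, ignore_index=True)


def cox_cohort(cohort: Cohort, het: pd.DataFrame,
               pcs: pd.DataFrame | None, analyses: tuple,
               n_pcs: int = 10) -> list[dict]:
    """All requested Cox fits for one cohort; the heterozygosity
    covariate is the raw statistic t, standardized post hoc via SD(t)."""
    pheno = cohort.phenotypes.copy()
    for col in ("education", "income", "center", "sex"):
        pheno[col] = pheno[col].astype(str)
    base = het[het["scope"] == "genome"][["iid", "t", "cohort_sd_t"]]
    d = pheno.merge(base.rename(columns={"t": "het_t"}), on="iid", how="inner")
    covs = ["het_t", "bmi"]
    if pcs is not None:
        pc_cols = [f"pc{j+1}" for j in range(n_pcs) if f"pc{j+1}" in pcs.columns]
        d = d.merge(pcs[["iid"] + pc_cols], on="iid", how="left")
        covs += pc_cols
    strata = survival.DEFAULT_STRATA

    def record(fit: survival.CoxFit, analysis: str, scope: str,
               sd_het: float) -> dict:
        rec = fit.term("het_t")
        rec.update(cohort=cohort.name, ancestry=cohort.ancestry,
                   analysis=analysis, scope=scope, sd_het=float(sd_het))
        return rec

    fits: list[dict] = []
    sd_t = float(base["cohort_sd_t"].iloc[0])
    if {"overall", "ancestry"} & set(analyses):
        fit = survival.cox_fit(d, covs, strata)
        fits.append(record(fit, "all_cause", "overall", sd_t))
    if "cause" in analyses:
        for cause in ("cancer", "cvd", "other"):
            try:
                fit = survival.cause_specific_fit(d, cause, covs, strata)
            except survival.CoxFitError:
                continue
            fits.append(record(fit, "cause", cause, sd_t))
    if "sex" in analyses:
        for sex in ("F", "M"):
            sub = d[d["sex"] == sex]
            if sub["dead"].sum() == 0:
                continue
            fit = survival.cox_fit(sub, covs, [s for s in strata if s != "sex"])
            fits.append(record(fit, "sex", sex, sd_t))
    if "chromosome" in analyses:
        chrom_scopes = [s for s in het["scope"].unique() if s.startswith("chr")]
        for scope in chrom_scopes:
            sub = het[het["scope"] == scope][["iid", "t", "cohort_sd_t"]]
            dc = d.drop(columns=["het_t", "cohort_sd_t"]).merge(
                sub.rename(columns={"t": "het_t"}), on="iid", how="inner")
            fit = survival.cox_fit(dc, covs, strata)
            fits.append(record(fit, "chromosome", scope,
                               float(sub["cohort_sd_t"].iloc[0])))
    return fits


def process_cohort(cohort: Cohort, config: StudyConfig) -> dict:
    """Run every per-cohort stage; returns fits plus QC artifacts."""
    keep, panel, report = snp_qc_cohort(cohort, config.qc)
    if keep.sum() == 0:
        raise PipelineError("snp_qc", f"{cohort.name}: no SNP passed QC")
    if config.do_sample_qc:
        sq = sample_qc_cohort(cohort, keep, n_pcs=config.n_pcs,
                              sd_threshold=config.sd_threshold,
                              kinship_threshold=config.kinship_threshold)
        retained = sq["retained_ids"]
        pcs = sq["pcs"] if config.include_pcs else None
    else:
        sq = None
        retained = [sid for sid, m in zip(cohort.sample_ids, cohort.study_mask) if m]
        pcs = None
    het = het_cohort(cohort, keep, retained)
    fits = cox_cohort(cohort, het, pcs, config.analyses, n_pcs=config.n_pcs)
    return {"fits": fits, "panel": panel, "snp_report": report,
            "sample_qc": sq, "het": het, "n_snps_kept": int(keep.sum()),
            "n_samples_kept": len(retained)}


# ---------------------------------------------------------------------------
# meta stage


def meta_stage(fits: list[dict], analyses: tuple = ANALYSES,
               stouffer_weight: str = "deaths") -> dict[str, pd.DataFrame]:
    """Group per-cohort fits into the study's five meta-analyses."""
    ests = meta.estimates_from_records
    by = lambda analysis: [f for f in fits if f["analysis"] == analysis]
    tables: dict[str, pd.DataFrame] = {}
    if "overall" in analyses:
        tables["overall"] = meta.meta_table(
            {"overall": ests(by("all_cause"))}, stouffer_weight)
    if "ancestry" in analyses:
        groups: dict[str, list] = {}
        for f in by("all_cause"):
            groups.setdefault(f["ancestry"], []).append(f)
        if len(groups) >= 2:
            tables["ancestry"] = meta.meta_table(
                {k: ests(v) for k, v in groups.items()}, stouffer_weight)
    for analysis in ("cause", "sex", "chromosome"):
        if analysis in analyses:
            groups = {}
            for f in by(analysis):
                groups.setdefault(f["scope"], []).append(f)
            if groups:
                tables[analysis] = meta.meta_table(
                    {k: ests(v) for k, v in groups.items()}, stouffer_weight)
    return tables


def subgroup_summary(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for name, df in tables.items():
        if "between_group_p" in df.attrs:
            rows.append({"analysis": name, "q": df.attrs["between_group_q"],
                         "df": df.attrs["between_group_df"],
                         "p": df.attrs["between_group_p"]})
    return pd.DataFrame(rows, columns=["analysis", "q", "df", "p"])


# ---------------------------------------------------------------------------
# end-to-end drivers


def run_study(config: StudyConfig, outdir: str | pathlib.Path,
              cohorts: list[Cohort] | None = None) -> dict:
    """Execute the full study and write fits, meta tables and a manifest.

    Returns the manifest dict.  ``cohorts`` may be supplied (e.g. read
    from disk); otherwise they are simulated from ``config.sim``.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "stages": {}, "version": _version()}
    try:
        if cohorts is None:
            cohorts = simulate_study(config.sim, config.seed)
        manifest["stages"]["simulate"] = {
            "cohorts": [c.name for c in cohorts],
            "n_individuals": [int(c.study_mask.sum()) for c in cohorts],
            "n_snps": [len(c.snp_ids) for c in cohorts]}
        if config.write_cohorts:
            for c in cohorts:
                write_cohort(c, outdir / "cohorts" / c.name, config.cohort_format)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("simulate", str(err)) from err

    all_fits: list[dict] = []
    fits_dir = outdir / "fits"
    fits_dir.mkdir(exist_ok=True)
    counts = {}
    for cohort in cohorts:
        try:
            res = process_cohort(cohort, config)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError("cohort", f"{cohort.name}: {err}") from err
        all_fits.extend(res["fits"])
        counts[cohort.name] = {"snps_kept": res["n_snps_kept"],
                               "samples_kept": res["n_samples_kept"],
                               "fits": len(res["fits"])}
        (fits_dir / f"{cohort.name}.json").write_text(
            json.dumps(res["fits"], indent=1))
        qc_dir = outdir / "qc"
        qc_dir.mkdir(exist_ok=True)
        res["panel"].to_csv(qc_dir / f"{cohort.name}_panel.tsv",
                            sep="\t", index=False)
        res["snp_report"].to_csv(qc_dir / f"{cohort.name}_snp_exclusions.tsv",
                                 sep="\t", index=False)
    manifest["stages"]["cohorts"] = counts

    try:
        tables = meta_stage(all_fits, config.analyses, config.stouffer_weight)
    except Exception as err:
        raise PipelineError("meta", str(err)) from err
    meta_dir = outdir / "meta"
    meta_dir.mkdir(exist_ok=True)
    for name, df in tables.items():
        df.to_csv(meta_dir / f"meta_{name}.tsv", sep="\t", index=False)
    subgroup_summary(tables).to_csv(meta_dir / "subgroup_tests.tsv",
                                    sep="\t", index=False)
    manifest["stages"]["meta"] = {"tables": sorted(tables),
                                  "n_fits_in": len(all_fits)}
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_cohorts(indir: str | pathlib.Path) -> list[Cohort]:
    """Read every cohort directory under ``indir`` (written by
    :func:`hetsurv.synthetic_data.write_cohort`)."""
    indir = pathlib.Path(indir)
    dirs = sorted(p for p in indir.iterdir() if (p / "cohort.json").exists())
    if not dirs:
        raise FileNotFoundError(f"no cohort directories under {indir}")
    return [read_cohort(p) for p in dirs]


def recovery_experiment(config: StudyConfig, n_replicates: int,
                        alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Repeated end-to-end runs against the planted per-SD log-HR.

    Each replicate simulates a fresh study (child seed), runs the full
    per-cohort pipeline and the overall meta-analysis, and records the
    combined standardized estimate with its CI and the Stouffer p.
    Summary reports CI coverage of the truth and the Stouffer rejection
    rate at ``alpha`` (the null-calibration rate when the truth is 0).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    truth = config.sim.true_log_hr_per_sd
    children = np.random.SeedSequence(config.seed).spawn(n_replicates)
    zcrit = float(-_norm_ppf(alpha / 2.0))
    rows = []
    for r, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        cohorts = simulate_study(config.sim, seed)
        fits = []
        for c in cohorts:
            fits.extend(process_cohort(c, config)["fits"])
        row = meta_stage(fits, ("overall",), config.stouffer_weight)["overall"].iloc[0]
        lo = row["beta_std"] - zcrit * row["se_std"]
        hi = row["beta_std"] + zcrit * row["se_std"]
        rows.append({"replicate": r, "beta_std": row["beta_std"],
                     "se_std": row["se_std"], "ci_lo": lo, "ci_hi": hi,
                     "covers": lo <= truth <= hi,
                     "stouffer_p": row["stouffer_p"],
                     "reject": row["stouffer_p"] < alpha})
    report = pd.DataFrame(rows)
    summary = {"true_log_hr_per_sd": truth,
               "n_replicates": n_replicates,
               "coverage": float(report["covers"].mean()),
               "rejection_rate": float(report["reject"].mean()),
               "mean_beta_std": float(report["beta_std"].mean())}
    return report, summary


def _norm_ppf(q: float) -> float:
    from scipy import stats
    return float(stats.norm.ppf(q))


def _version() -> str:
    from . import __version__
    return __version__
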