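"""Heterozygosity scoring per cohort.

Computes the HWE-normalized statistic t = (#het loci) / sum 2p(1-p) for
every retained individual, genome-wide and per chromosome, standardized
within cohort.  Under random mating E[t] ~ 1; the cohort SD of t is the
quantity that later standardizes the Cox effect sizes.  Writes
results/het/<cohort>_het.tsv.
"""

import pathlib
import sys

import numpy as np
import pandas as pd

from hetsurv import pipeline as pl

ROOT = pathlib.Path(__file__).resolve().parents[1]
QC = ROOT / "results" / "qc"
HET = ROOT / "results" / "het"


def main() -> int:
    HET.mkdir(parents=True, exist_ok=True)
    for cohort in pl.load_cohorts(ROOT / "results" / "cohorts"):
        panel = pd.read_csv(QC / f"{cohort.name}_panel.tsv", sep="\t")
        keep = np.isin(np.asarray(cohort.snp_ids), panel["snp_id"].to_numpy())
        retained = pd.read_csv(QC / f"{cohort.name}_retained.tsv",
                               sep="\t")["iid"].tolist()
        het = pl.het_cohort(cohort, keep, retained)
        het.to_csv(HET / f"{cohort.name}_het.tsv", sep="\t", index=False)
        g = het[het["scope"] == "genome"]
        print(f"{cohort.name}: mean t = {g['t'].mean():.4f} "
              f"(HWE expectation 1), SD(t) = {g['t'].std(ddof=1):.4f}, "
              f"{g['n_loci_used'].median():.0f} loci/individual")
    print(f"\nscores under {HET}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
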