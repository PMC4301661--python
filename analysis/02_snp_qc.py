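"""SNP quality control per cohort.

Applies the exclusion rules (monomorphic, >0.5% missingness, MAF <= 10%,
HWE p < 0.001, non-autosomal) to each cohort's study samples and writes
the surviving panel and the per-reason exclusion report under
results/qc/.
"""

import pathlib
import sys

from hetsurv import genotype_qc as gq
from hetsurv import pipeline as pl

ROOT = pathlib.Path(__file__).resolve().parents[1]
QC = ROOT / "results" / "qc"


def main() -> int:
    QC.mkdir(parents=True, exist_ok=True)
    for cohort in pl.load_cohorts(ROOT / "results" / "cohorts"):
        keep, panel, report = pl.snp_qc_cohort(cohort, gq.QCThresholds())
        panel.to_csv(QC / f"{cohort.name}_panel.tsv", sep="\t", index=False)
        report.to_csv(QC / f"{cohort.name}_snp_exclusions.tsv", sep="\t",
                      index=False)
        counts = gq.reason_counts(report)
        reasons = ", ".join(f"{k}={v}" for k, v in counts.items()) or "none"
        print(f"{cohort.name}: {int(keep.sum())}/{len(cohort.snp_ids)} SNPs "
              f"pass ({reasons})")
    print(f"\npanels and exclusion reports under {QC}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
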