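"""Sample quality control per cohort.

PCA of the combined study + reference matrix, genetic-outlier exclusion
(explained-variance-weighted distance from the matching reference
centroid, 10-SD rule) and kinship-based pruning of first/second-degree
relatives.  Writes PC scores, the outlier report, over-threshold kinship
pairs and the retained sample list under results/qc/.
"""

import pathlib
import sys

import numpy as np
import pandas as pd

from hetsurv import pipeline as pl

ROOT = pathlib.Path(__file__).resolve().parents[1]
QC = ROOT / "results" / "qc"


def main() -> int:
    for cohort in pl.load_cohorts(ROOT / "results" / "cohorts"):
        panel = pd.read_csv(QC / f"{cohort.name}_panel.tsv", sep="\t")
        keep = np.isin(np.asarray(cohort.snp_ids),
                       panel["snp_id"].to_numpy())
        sq = pl.sample_qc_cohort(cohort, keep)
        sq["pcs"].to_csv(QC / f"{cohort.name}_pcs.tsv", sep="\t", index=False)
        sq["outliers"].to_csv(QC / f"{cohort.name}_outliers.tsv", sep="\t",
                              index=False)
        sq["kinship_pairs"].to_csv(QC / f"{cohort.name}_kinship_pairs.tsv",
                                   sep="\t", index=False)
        pd.Series(sq["retained_ids"], name="iid").to_csv(
            QC / f"{cohort.name}_retained.tsv", sep="\t", index=False)
        print(f"{cohort.name}: {sq['n_excluded_outlier']} PC outliers, "
              f"{sq['n_excluded_related']} relatives pruned, "
              f"{len(sq['retained_ids'])} study samples retained "
              f"(PC1 explains {sq['explained_var'][0]:.1%})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
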