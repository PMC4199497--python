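"""Group comparisons and clinical regressions.

Welch unequal-variance t-tests (control vs patient) per metric and
band, Holm-corrected across bands within each metric family;
within-group NMI contrasts; robust regressions of alpha-network
metrics on CRS-R. Writes results/group_tests.csv,
results/regressions.csv and the markdown report results/report.md.

    python analysis/06_group_stats.py
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from eegspan.io import read_subject_table  # noqa: E402
from eegspan.pipeline import CohortAnalysis, cohort_report  # noqa: E402
from eegspan.io import load_montage  # noqa: E402


def main():
    res = ROOT / "results"
    records = read_subject_table(res / "cohort" / "subjects.csv")
    order = [r.subject_id for r in records]
    metrics = pd.read_csv(res / "graph_metrics.csv")
    nmi = {}
    for path in res.glob("nmi_*.csv"):
        frame = pd.read_csv(path, index_col=0)
        nmi[path.stem.split("_", 1)[1]] = frame.loc[order, order].to_numpy()
    mean_dwpli = pd.read_csv(res / "mean_dwpli.csv", index_col=0).loc[order]
    analysis = CohortAnalysis(
        montage=load_montage(res / "cohort" / "montage.txt"),
        records=records,
        truths=[],
        power=pd.read_csv(res / "power_contributions.csv", index_col=0).loc[order],
        variability=pd.read_csv(res / "power_variability.csv", index_col=0).loc[order],
        mean_dwpli=mean_dwpli,
        metrics=metrics.set_index("subject_id").loc[order].reset_index(),
        nmi=nmi,
    )
    report = cohort_report(analysis)
    report.group_tests.to_csv(res / "group_tests.csv", index=False)
    report.regressions.to_csv(res / "regressions.csv", index=False)
    (res / "report.md").write_text(report.markdown)
    cols = ["metric", "band", "t", "p_corrected", "mean_a", "mean_b"]
    print(report.group_tests[cols].round(4).to_string(index=False))
    if len(report.regressions):
        print(report.regressions[["predictor", "subset", "slope",
                                  "r_squared", "p_slope"]].round(4)
              .to_string(index=False))


if __name__ == "__main__":
    main()
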