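#!/usr/bin/env python
"""Out-of-sample prediction from the extracted coupling estimates.

Leave-one-out multiple regression of precision-grip performance and of
age in months on the 14 couplings, and leave-one-out QDA classification
of age group with an exact binomial test against the no-information
rate. Outputs: results/prediction.json.
"""

import json
from pathlib import Path

import pandas as pd

from gripdcm.prediction import FeatureTable, loocv_regression, qda_loocv

if __name__ == "__main__":
    df = pd.read_csv("results/subject_estimates.csv")
    table = FeatureTable.from_frame(df.rename(columns={"subject": "subject_id"}))

    reg_perf = loocv_regression(table, "performance")
    reg_age = loocv_regression(table, "age_months")
    cm = qda_loocv(table)

    out = {
        "performance": {"rmse": reg_perf.rmse, "r2": reg_perf.r2,
                        "r2_ss": reg_perf.r2_ss},
        "age_months": {"rmse": reg_age.rmse, "r2": reg_age.r2,
                       "r2_ss": reg_age.r2_ss},
        "qda": {"accuracy": cm.accuracy, "ci95": list(cm.ci95), "nir": cm.nir,
                "p_vs_nir": cm.p_vs_nir, "labels": list(cm.labels),
                "confusion": cm.counts.tolist(),
                "confusion_normalized": cm.normalized().tolist()},
    }
    Path("results/prediction.json").write_text(json.dumps(out, indent=2))
    print(f"performance: LOOCV RMSE = {reg_perf.rmse:.3f} a.u., R² = {reg_perf.r2:.2f}")
    print(f"age:         LOOCV RMSE = {reg_age.rmse:.1f} months, R² = {reg_age.r2:.2f}")
    print(f"QDA accuracy = {cm.accuracy:.2f} (CI [{cm.ci95[0]:.2f} {cm.ci95[1]:.2f}]), "
          f"p vs NIR = {cm.p_vs_nir:.2e}")
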