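"""Survival analysis of the radiomics biomarkers.

Kaplan-Meier curves and log-rank tests across the four radiomics immune
subtypes, univariate and multivariate Cox models for the LRS/MRS (with the
Schoenfeld PH check), and the nomogram (LRS + MRS + TNM stage) C-index.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import COVARIATE_COLUMNS, RESULTS, ensure_dirs

from immunorad import (concordance_index, cox_fit, km_estimate, logrank_test,
                       nomogram_model, ph_test)


def main():
    ensure_dirs()
    cohort = pd.read_csv(RESULTS / "cohort.csv", index_col="patient_id")
    scores = pd.read_csv(RESULTS / "radiomics_scores.csv",
                         index_col="patient_id")
    df = cohort.join(scores[["lrs", "mrs", "subtype"]], rsuffix="_radiomics")
    t, e = df["survival_time"].to_numpy(), df["event"].to_numpy()

    chi2, dof, p = logrank_test(t, e, scores["subtype"])
    print(f"log-rank across 4 radiomics subtypes: chi2 {chi2:.2f} "
          f"(df {dof}), p {p:.4f}")
    km_rows = []
    for s, g in df.groupby(scores["subtype"]):
        km = km_estimate(g["survival_time"], g["event"])
        km_rows.append({"subtype": s, "n": len(g),
                        "surv_36m": km.survival_at(36.0)})
    km_df = pd.DataFrame(km_rows).set_index("subtype")
    km_df.to_csv(RESULTS / "km_by_subtype.csv")
    print("36-month survival by subtype:",
          {s: round(v, 3) for s, v in km_df["surv_36m"].items()})

    X_uni = df[["lrs"]].copy()
    uni = cox_fit(X_uni, t, e).summary()
    X = df[["lrs", "mrs"] + COVARIATE_COLUMNS].astype(float)
    res = cox_fit(X, t, e)
    summ = res.summary()
    summ.to_csv(RESULTS / "cox_multivariate.csv", index_label="covariate")
    for name in ("lrs", "mrs"):
        row = summ.loc[name]
        print(f"multivariate Cox {name.upper()}: HR {row.hr:.3f} "
              f"({row.hr_ci_low:.3f}-{row.hr_ci_high:.3f}), p {row.p:.4f}")
    print(f"univariate LRS HR {uni.loc['lrs','hr']:.3f}")

    ph = ph_test(res)
    print(f"PH assumption: global chi2 {ph.global_chi2:.2f}, "
          f"p {ph.global_p:.3f} -> {ph.verdict}")

    nomo_X = df[["lrs", "mrs", "tnm_stage"]].astype(float)
    nomo_fit = cox_fit(nomo_X, t, e)
    nomo = nomogram_model(nomo_fit, nomo_X)
    c_nomo = concordance_index(nomo.total_points(nomo_X), t, e)
    c_stage = concordance_index(df["tnm_stage"].to_numpy(dtype=float), t, e)
    print(f"nomogram (LRS+MRS+stage) C-index {c_nomo:.3f} vs TNM stage "
          f"alone {c_stage:.3f}")
    pd.Series({"c_index_nomogram": c_nomo, "c_index_stage": c_stage}).to_csv(
        RESULTS / "nomogram_cindex.csv", header=False)


if __name__ == "__main__":
    main()
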