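"""Immunotherapy response: ORR by radiomics group and the CPS comparison.

Objective response rates across LRS/MRS statuses and the four subtypes,
and the DeLong comparison of PD-L1 CPS against the fitted LRS+MRS
combination and the integrative CPS+LRS+MRS model.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, ensure_dirs

from immunorad import compare_auc, logistic_combination, orr_table, roc_auc


def main():
    ensure_dirs()
    cohort = pd.read_csv(RESULTS / "cohort.csv", index_col="patient_id")
    scores = pd.read_csv(RESULTS / "radiomics_scores.csv",
                         index_col="patient_id")
    df = cohort.join(scores[["lrs", "mrs", "lrs_status", "mrs_status"]],
                     rsuffix="_r")
    io = df[df["immunotherapy"] == 1].copy()
    io["subtype_r"] = scores.loc[io.index, "subtype"]
    print(f"immunotherapy cohort: n = {len(io)}")

    for group in ("lrs_status", "mrs_status", "subtype_r"):
        table, p, test = orr_table(io["response"], io[group])
        pretty = ", ".join(f"{g}: {r:.1f}%" for g, r in
                           table["orr_percent"].items())
        print(f"ORR by {group}: {pretty}  ({test} p = {p:.4f})")
        table.to_csv(RESULTS / f"orr_by_{group}.csv")

    y = io["response"].isin(["CR", "PR"]).astype(int).to_numpy()
    cps = io["cps"].to_numpy()
    combo = logistic_combination(io[["lrs", "mrs"]], y)
    integrative = logistic_combination(io[["cps", "lrs", "mrs"]], y)

    auc_cps = roc_auc(cps, y)
    print(f"CPS alone: AUC {auc_cps.auc:.3f} "
          f"({auc_cps.ci_low:.3f}-{auc_cps.ci_high:.3f})")
    res = compare_auc(combo, cps, y)
    print(f"LRS+MRS combination: AUC {res.auc_a:.3f} vs CPS {res.auc_b:.3f} "
          f"(DeLong p = {res.p_value:.4f})")
    res2 = compare_auc(integrative, cps, y)
    print(f"integrative CPS+LRS+MRS: AUC {res2.auc_a:.3f} vs CPS "
          f"(DeLong p = {res2.p_value:.4f})")
    pd.Series({"auc_cps": res.auc_b, "auc_lrs_mrs": res.auc_a,
               "auc_integrative": res2.auc_a, "p_combo_vs_cps": res.p_value,
               "p_integrative_vs_cps": res2.p_value}).to_csv(
        RESULTS / "auc_comparison.csv", header=False)


if __name__ == "__main__":
    main()
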