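"""Train the lymphoid and myeloid radiomics scores (LRS / MRS).

Runs the selection cascade (ICC filter -> mRMR -> collinearity reduction ->
LASSO & SVM-RFE with 5-fold CV -> overlap -> multivariate logistic) against
the IHC-derived LIS/MIS statuses, derives Youden cutoffs (plus
median/quartile alternatives), assigns the four radiomics immune subtypes
and reports training AUCs.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH, STUDY_CONFIG, ensure_dirs

from immunorad import (alternative_cutoffs, assign_subtype, roc_auc,
                       train_signature)


def main():
    ensure_dirs()
    feats = pd.read_csv(SCRATCH / "features.csv", index_col="patient_id")
    cohort = pd.read_csv(RESULTS / "cohort.csv", index_col="patient_id")
    icc_pass = (RESULTS / "icc_pass.txt").read_text().splitlines()

    scores = pd.DataFrame(index=feats.index)
    for target, label_col, name in (("lymphoid", "lis_status", "lrs"),
                                    ("myeloid", "mis_status", "mrs")):
        y = (cohort[label_col] == "high").astype(int).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, sel = train_signature(feats, y, target,
                                         seed=STUDY_CONFIG.seed,
                                         icc_pass=icc_pass, k_mrmr=30)
        model.to_json(RESULTS / f"{name}_model.json")
        s = model.score(feats)
        scores[name] = s
        scores[f"{name}_status"] = model.status(feats)
        auc = roc_auc(s, y)
        n_intra = sum(f.startswith("intra_") for f in model.feature_names)
        n_peri = len(model.feature_names) - n_intra
        print(f"{name.upper()}: {n_intra} intratumoral + {n_peri} peritumoral "
              f"features, training AUC {auc.auc:.3f} "
              f"({auc.ci_low:.3f}-{auc.ci_high:.3f}), "
              f"Youden cutoff {model.cutoff:.4f}")
        alt = alternative_cutoffs(s)
        print(f"  alternative cutoffs: median {alt['median']:.4f}, "
              f"upper quartile {alt['upper_quartile']:.4f}, "
              f"lower quartile {alt['lower_quartile']:.4f}")
        print(f"  cascade: {len(sel.icc_pass)} ICC-pass -> "
              f"{len(sel.mrmr_top)} mRMR -> {len(sel.decorrelated)} "
              f"decorrelated -> LASSO {len(sel.lasso_set)} / SVM-RFE "
              f"{len(sel.svmrfe_set)} -> overlap {len(sel.overlap_set)}"
              + (" (fallback to LASSO set)" if sel.used_fallback else ""))

    scores["subtype"] = [assign_subtype(l, m) for l, m in
                         zip(scores["lrs_status"], scores["mrs_status"])]
    scores.to_csv(RESULTS / "radiomics_scores.csv", index_label="patient_id")
    agree = (scores["subtype"].to_numpy()
             == cohort["subtype"].to_numpy()).mean()
    print(f"radiomics subtype matches IHC-derived subtype for {agree:.0%} "
          f"of patients")


if __name__ == "__main__":
    main()
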