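"""Simulate the synthetic study cohort.

Generates 80 phantom patients (CT stand-in volumes + tumor masks, IHC
counts, covariates, survival, immunotherapy responses) under the shared
study configuration, writes the cohort table to results/cohort.csv and the
NIfTI images to scratch/cohort_images/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH, STUDY_CONFIG, ensure_dirs

from immunorad import cohort_table, generate_cohort, save_cohort


def main():
    ensure_dirs()
    patients = generate_cohort(STUDY_CONFIG)
    df = cohort_table(patients)
    save_cohort(patients, SCRATCH / "cohort_images", STUDY_CONFIG)
    (SCRATCH / "cohort_images" / "cohort.csv").rename(RESULTS / "cohort.csv")

    print(f"simulated {len(patients)} patients "
          f"(seed {STUDY_CONFIG.seed}, rho {STUDY_CONFIG.rho})")
    print("subtype counts:", df["subtype"].value_counts().sort_index().to_dict())
    print("LIS high:", (df.lis_status == 'high').mean().round(3),
          "| MIS high:", (df.mis_status == 'high').mean().round(3))
    print("event rate:", df["event"].mean().round(3),
          "| immunotherapy n =", int(df["immunotherapy"].sum()))
    print(f"wrote {RESULTS / 'cohort.csv'} and NIfTI images under "
          f"{SCRATCH / 'cohort_images'}")


if __name__ == "__main__":
    main()
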