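# immunorad

CT radiomics biomarkers of the tumor immune microenvironment in gastric
cancer — a tested re-implementation of the full analysis pipeline, from 3D
tumor masks to survival and immunotherapy-response statistics, with a
synthetic phantom-cohort generator in place of the original private
multi-center imaging/IHC data.

## The problem

The density of tumor-infiltrating lymphocytes (CD3+/CD8+) and neutrophils
(CD66b+) — the lymphoid and myeloid immune context — predicts prognosis and
anti–PD-1 response in gastric cancer, but measuring it requires invasive
tissue sampling. The pipeline builds two noninvasive CT imaging biomarkers:

* **LRS** (lymphoid radiomics score) and **MRS** (myeloid radiomics score):
  logistic linear predictors over selected intratumoral and peritumoral CT
  texture features, trained against median-dichotomized IHC immune scores
  (LIS ∈ 0–4 from CD3/CD8 counts in two regions; MIS ∈ 0–2 from CD66b);
* four **radiomics immune subtypes** from the dichotomized pair
  (LRS, MRS): 1 (−/−), 2 (+/−), 3 (−/+), 4 (+/+).

The stages, each a module in `src/immunorad/`:

| stage | module | what it does |
|---|---|---|
| regions | `geometry` | isotropic resampling; 3 mm peritumoral band (2 mm dilation + 1 mm inner shrinkage) via Euclidean distance transforms |
| features | `features`, `texture`, `icc` | 584-feature inventory (292 per region: 8 shape, 14 first-order, 270 texture = 90 statistics × bin counts {16, 32, 64}); ICC(2,1) reproducibility |
| signatures | `signature`, `roc` | mRMR → collinearity pruning → LASSO ∩ SVM-RFE (5-fold CV) → multivariate logistic; Youden cutoff; subtype assignment; DeLong AUC |
| immune context | `ihc` | LIS/MIS scoring from marker counts vs frozen training medians |
| outcomes | `survival`, `response`, `shapley` | Kaplan–Meier/log-rank, Breslow/Efron Cox with Schoenfeld PH test, Harrell's C, nomogram points, ORR tables, CPS-vs-radiomics DeLong comparison, exact Shapley attribution |
| synthetic data | `synthetic`, `grids` | phantom cohorts whose texture, IHC counts, survival and responses all derive from a latent bivariate (lymphoid, myeloid) context |

## Worked example

```python
import numpy as np, pandas as pd
from immunorad import (SyntheticConfig, generate_cohort, build_peritumoral_ring,
                       extract_feature_vector, train_signature, roc_auc)

cfg = SyntheticConfig(n_patients=80, seed=20240501,
                      semi_axis_range_mm=(8, 12))
patients = generate_cohort(cfg)
X = pd.DataFrame([extract_feature_vector(p.volume,
                                         build_peritumoral_ring(p.tumor_mask))
                  for p in patients])
y = np.array([p.lis_status == "high" for p in patients]).astype(int)
model, cascade = train_signature(X, y, "lymphoid", seed=20240501)
print(len(X.columns), roc_auc(model.score(X), y).auc)
```

prints `584` (the full feature inventory) and the training AUC of the
lymphoid signature. The numbered scripts under `analysis/` run the same
study end to end on the shared 80-patient synthetic cohort; on this cohort
they print, among other things:

```
LRS: 3 intratumoral + 1 peritumoral features, training AUC 0.962 (0.923-1.000)
MRS: 2 intratumoral + 1 peritumoral features, training AUC 0.843 (0.735-0.950)
multivariate Cox LRS: HR 0.814 (0.724-0.915), p 0.0006
PH assumption: global chi2 6.95, p 0.542 -> valid
ORR by subtype_r: 4: 26.1%, 2: 50.0%, 1: 0.0%, 3: 20.0%
lymphoid context — mean |Shapley| ranking: lrs: 6.939, tumor_size_mm: 2.060, ...
```

i.e. the signatures discriminate the IHC-derived immune statuses, a high
LRS is protective (HR < 1) and a high MRS adverse in multivariate Cox, the
proportional-hazards assumption holds, subtype 2 (+/−) responds best to
immunotherapy, and each radiomics score dominates the clinical covariates
in the Shapley attribution — the qualitative pattern the biomarkers are
designed to capture. Run them in order:

```bash
python analysis/01_simulate_cohort.py      # cohort -> results/cohort.csv
python analysis/02_extract_features.py     # 584 features + ICC filter
python analysis/03_train_signatures.py     # LRS/MRS + cutoffs + subtypes
python analysis/04_outcome_analysis.py     # KM, Cox, PH, nomogram C-index
python analysis/05_response_analysis.py    # ORR tables, CPS vs radiomics AUC
python analysis/06_interpretability.py     # exact Shapley importance
```

Tables land in `results/`; bulky intermediates (NIfTI phantoms, the raw
feature matrix) in `scratch/`.

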