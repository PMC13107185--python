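"""Prognostic modelling: subtype + stage Cox model, three-class risk
staging, and mode-restricted ridge-Cox risk scores.

On a cohort where only US-mode proteins express the latent hazard, the
US-restricted ridge model should beat models built on other mode sets in
the held-out test cohort.
"""

import numpy as np

from escctraj import (SimConfig, assign_modes, generate_cohort, logrank_test,
                      staging_3c, train_test_split, wilcoxon_de)
from escctraj.evaluate import (compare_mode_models, patient_feature_table,
                               subtype_ptnm_model)

# --- subtype + pTNM Cox model and 3-class restaging ----------------------
# Default cohort: the NAT subtype carries a planted hazard ratio of 2.
_, _, clinical_hr, truth_hr = generate_cohort(SimConfig(seed=3))
model, risk = subtype_ptnm_model(clinical_hr, truth_hr.subtype_label)
print("subtype + pTNM Cox model (planted subtype HR = 2):")
print(model.summary[["hr", "hr_ci_low", "hr_ci_high", "p"]].round(3))
staging = staging_3c(risk, seed=1)
clin = clinical_hr.set_index("patient_id")
chi2, df, p = logrank_test(clin.loc[staging.groups.index, "os_time"],
                           clin.loc[staging.groups.index, "os_event"],
                           staging.groups)
print(f"3-class restaging log-rank: chi2={chi2:.2f} (df={df}), p={p:.3g}")

# --- mode-restricted ridge-Cox models on the NAT proteome ----------------
# Risk scenario: hazard driven by a latent factor expressed in US proteins.
cfg = SimConfig(seed=5, subtype_hr=1.0, risk_beta=0.7)
matrix, meta, clinical, truth = generate_cohort(cfg)
samples = lambda t: meta.loc[meta.tissue == t, "sample_id"].tolist()
am = assign_modes(wilcoxon_de(matrix, samples("NAT"), samples("Healthy")),
                  wilcoxon_de(matrix, samples("Tumor"), samples("NAT")))
feats = patient_feature_table(matrix, meta, "NAT")
train, test, _ = train_test_split(clinical, seed=5)
res = compare_mode_models(feats, am, clinical, train, test, endpoint="OS",
                          lambda_grid=np.geomspace(1, 1000, 5), nfolds=5,
                          seed=5)
print("\ntest-cohort C-index per mode-restricted model:")
print(res["cindex_test"].round(3).sort_values(ascending=False).to_string())
print("\nThe US model leads because the latent risk was planted in "
      "US-mode proteins only.")
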