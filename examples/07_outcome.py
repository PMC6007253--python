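"""Rapid-metastasis prediction and Kaplan-Meier stratification.

Generates an ADT outcome cohort in which planted transcripts carry the
event hazard only in treated patients, then computes the rapid-metastasis
(< 36 months) ROC AUC and the median-split log-rank test in each arm.
"""

from netdlnc.clinical import define_rapid_met_groups, km_median_split, roc_auc
from netdlnc.synthetic_data import SimulationConfig, generate_outcome_cohort

config = SimulationConfig(seed=1, outcome_hazard_fold=8.0, n_outcome_samples=200)
matrix, metadata, truth = generate_outcome_cohort(config)
transcript = truth.index[truth.planted_class == "outcome"][0]

for arm in ("treated", "untreated"):
    labels = define_rapid_met_groups(metadata, arm=arm).dropna()
    auc = roc_auc(matrix.loc[transcript, labels.index], labels.astype(bool))
    _curves, p = km_median_split(matrix.loc[transcript], metadata, arm)
    print(f"{arm:>10} arm: rapid-met AUC = {auc:.3f} "
          f"(n={len(labels)}), median-split log-rank p = {p:.4f}")

# The planted transcript predicts rapid metastasis only where the hazard
# was attached (the ADT-treated arm); the untreated arm behaves as a null
# control with AUC near 0.5 and a non-significant log-rank test.
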