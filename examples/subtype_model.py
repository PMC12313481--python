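"""Fit and evaluate a LASSO-logistic Radscore on a synthetic cohort.

Simulates a 200-patient cohort where 5 of 100 features separate the two
outcome classes by a standardized effect of 1.5, splits 7:3 stratified,
screens and fits on the training rows only, and reports ROC and
decision-curve summaries on the held-out test set.
"""

from kinhet import CohortSpec, SplitSpec, run_subtype_task, simulate_feature_cohort

cohort = simulate_feature_cohort(CohortSpec(seed=21, feature_effect=1.5))
result = run_subtype_task(cohort.table, cohort.labels, SplitSpec(seed=21))

m = result.model
print(f"selected {len(m.selected)} features at lambda = {m.lambda_:.4f}")
print(f"true informative columns recovered: "
      f"{sorted(set(m.selected) & set(cohort.informative))}")

for split, roc in [("train", result.train_roc), ("test", result.test_roc)]:
    print(f"{split}: AUC {roc.auc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f}), "
          f"sens {roc.sensitivity:.2f} spec {roc.specificity:.2f} "
          f"PPV {roc.ppv:.2f} NPV {roc.npv:.2f} acc {roc.accuracy:.2f}")
# test AUC well above 0.5 shows the signal generalizes; the Youden-index
# cutoff fixes the reported operating point.

dca = result.test_dca
row = dca.iloc[(dca["threshold"] - 0.5).abs().idxmin()]
print(f"net benefit at p_t=0.5: model {row['net_benefit']:.3f}, "
      f"treat-all {row['treat_all']:.3f}, treat-none {row['treat_none']:.1f}")
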