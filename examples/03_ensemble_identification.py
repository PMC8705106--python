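"""Identify subjects from gait features with ensemble classifiers.

Builds a 20-subject cohort (12 cycles each, the scale of a small gait
dataset), extracts cycles and features, reports class separability and the
held-out accuracy of the three ensemble methods with their fixed
hyperparameters, plus the most informative features.
"""

from gaitid.classify import evaluate_repeated, separability
from gaitid.cycles import extract_cycles
from gaitid.features import feature_table
from gaitid.synthetic import CohortSpec, generate_cohort

seqs, truth = generate_cohort(CohortSpec(n_subjects=20, cycles_per_subject=12, seed=5))
table = feature_table([(s.subject_id, extract_cycles(s)) for s in seqs])
print(f"feature table: {len(table)} cycles x {table.matrix.shape[1]} features")

sep = separability(table)
print(f"class separability psi (z-scored features): {sep.psi:.1f} "
      "(positive: classes sit further apart than they spread)")

for method in ("random_forest", "xgboost", "lightgbm"):
    rep = evaluate_repeated(table, method=method, repeats=10, seed=42)
    print(f"{method:15s} mean held-out accuracy {rep.accuracy:.3f} "
          f"(sd {rep.accuracy_sd:.3f}), macro F1 {rep.f1:.3f}")
    print(f"{'':15s} top features: {', '.join(rep.importance_ranking[:5])}")

# Accuracies near 1.0 show the feature catalogue separates subjects whose
# stride, cadence and limb proportions differ at realistic between-subject
# spreads; the importance ranking echoes that length and stride features
# carry more identity signal than phase-anchored angles.
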