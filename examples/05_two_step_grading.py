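"""Train the two-step grade classifiers on a feature-level phantom.

The grade signal is planted only in the habitat feature blocks, so the
habitat classifier should beat the whole-volume classifier, and the
combined classifier should match or exceed both — the qualitative
ordering the habitat approach is designed to produce.
"""

from habicat import evaluate_two_step, generate_feature_table, shap_linear, train_two_step

table = generate_feature_table(n_per_grade=50, signal="habitat",
                               effect_size=1.0, seed=0)
result = train_two_step(table, seed=0)
report = evaluate_two_step(result, table)

m = report.rounded()
print(m[m.split == "test"][
    ["model", "classifier", "AUC", "CI_low", "CI_high",
     "SENS", "SPEC", "BACC"]
].to_string(index=False))

mat = report.delong_matrices["model1"].round(3)
print("\nDeLong p-values, model 1 (grade 3 vs 1-2) test split:")
print(mat.to_string())

clf = result.classifiers["model1"]["Clf_Total"]
_, summary = shap_linear(clf, table)
print("\ntop features of Clf_Total by mean |SHAP| (log-odds units):")
print(summary.head(5).round(3).to_string(index=False))
print("\nHabitat-block features dominating the ranking reflects where the "
      "signal was planted.")
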