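"""Cross-validated evaluation: the headline numbers of the framework.

Runs the full 10-fold protocol -- scale correction off, supervised graph,
NPE, rotation, GP age regression, LDA sex classification, all refit inside
every training fold -- and prints the pooled out-of-fold metrics, the
age-binned accuracy table and the site ANOVA.
"""

from npembed import GeneratorSpec, RunConfig, crossval_evaluate, generate_cohort

table, matrices, _ = generate_cohort(GeneratorSpec(n_subjects=300, seed=1))
report = crossval_evaluate(table, matrices, RunConfig(random_seed=1))

print(f"n = {report.n_subjects}, 10-fold cross-validation")
print(f"age: MAE = {report.mae:.2f} y, Pearson r = {report.pearson_r:.3f}")
print(f"sex: accuracy = {report.accuracy:.1%}")
a = report.site_anova
print(f"site ANOVA on |age error|: F_{a['df1']},{a['df2']} = {a['F']:.2f}, "
      f"p = {a['p']:.2f}")
print("\nbin  n   mean age  MAE   accuracy")
for row in report.binned:
    print(f"{row['bin']:2d}  {row['n']:3d}  {row['mean_age']:7.2f}  "
          f"{row['mae']:.2f}  {row['accuracy']:.2f}")
print("\nMAE per age bin shows where the model is most precise; a "
      "non-significant site ANOVA means scanner identity does not bias the "
      "age-gap estimates.")
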