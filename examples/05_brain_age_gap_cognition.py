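"""Relate the brain-age gap to cognitive scores.

The predicted-age error (predicted minus chronological age) is an
individual index of apparent developmental advance or delay.  Each
cognitive score is first residualized on age, sex and socioeconomic status;
a simple regression of the residualized score on the age gap then asks
whether deviation from the typical trajectory carries cognitive
information.  In the simulated cohort scores are generated independent of
the brain patterns, so the expected answer is "no" -- a calibration check.
"""

import numpy as np

from npembed import (GeneratorSpec, RunConfig, crossval_evaluate,
                     error_cognition_regression, generate_cohort)
from npembed.simulate import COGNITIVE_SCORES

table, matrices, _ = generate_cohort(GeneratorSpec(n_subjects=300, seed=1))
report = crossval_evaluate(table, matrices, RunConfig(random_seed=1))

preds = report.predictions_frame().set_index("subject_id")
error = preds.loc[table.subject_ids, "error"].to_numpy()

df = error_cognition_regression(error, table, list(COGNITIVE_SCORES))
print("score                        R^2      F(1,n-2)   p       signif.")
for _, r in df.iterrows():
    print(f"{r['score']:27s}  {r['r2']:.4f}  {r['F']:8.3f}  {r['p']:.3f}   "
          f"{'*' if r['significant_bonferroni'] else '-'}")
print(f"\n{int(df['significant_bonferroni'].sum())} of {len(df)} scores "
      "significant after Bonferroni correction (expected 0: the simulated "
      "scores share no variance with the brain patterns).")
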