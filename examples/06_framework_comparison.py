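"""Compare training frameworks under patient-wise cross-validation.

Runs a deliberately small study (8 subjects, 2 folds, short schedules) so it
finishes in about a minute; the acceptance script runs the fuller version.
"""

from segpretext.experiment import StudyScale, compare_frameworks, run_study
from segpretext.synthetic_data import PhantomConfig, cohort_slices

cohort = cohort_slices(PhantomConfig(seed=7), 8)
scale = StudyScale(finetune_steps=80, proxy_steps=40)
report = run_study(cohort, frameworks=("non", "selflearn"), k=2, seed=0, scale=scale)

print(report.groupby("framework")["dice"].agg(["mean", "std", "min"]).round(3))
tables = compare_frameworks(report)
print(tables["pairwise"][["framework_a", "framework_b", "mean_diff", "p", "significant"]]
      .to_string(index=False))
# Per-subject Dice rows are paired across frameworks (same folds, same test
# subjects), so the paired t-test asks: does pretraining change this exact
# cohort's scores?
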