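"""Tune and train the PCA/ICA + kNN classifier on a fixed signature.

The tuning MCCV compares every (reduction, d, k) grid point on identical
per-round splits by mean validation minority-class F1; the final model is
then trained per round and evaluated on the untouched test set.
"""

from srmrad import (
    GeneratorConfig,
    SplitSpec,
    default_grid,
    generate_cohort,
    run_fs_mccv,
    run_training_mccv,
    select_signature,
    stratified_split,
    tune,
)

cohort = generate_cohort(GeneratorConfig(seed=0))
train, test = stratified_split(cohort, SplitSpec(0.2, True, 0))
signature = select_signature(run_fs_mccv(train, 25, base_seed=100), 10)

result = tune(train, signature, default_grid(("pca", "ica"), (2,), (3, 5, 7, 9)),
              rounds=25, base_seed=200)
print("tuning curve (mean validation F1 per grid point):")
print(result.curve.round(3).to_string(index=False))
print(f"\nbest: {result.best.reduction.upper()} d={result.best.d} k={result.best.k}")

perf = run_training_mccv(train, signature, result.best, rounds=25,
                         base_seed=300, test_set=test)
print("\nmean ± sd over 25 rounds (malignant positive; F1 on benign):")
print(perf.summary().round(2).to_string())
# Validation and test columns should broadly agree; a large gap would flag
# overfitting of the tuning step to the validation subsets.
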