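# srmrad

Radiomic-signature development for **small renal masses** (SRMs, renal
tumors < 4 cm): a tested, reusable implementation of a benign-vs-malignant
classification pipeline for CT radiomic feature tables.

Imaging alone discriminates benign SRMs (oncocytoma, lipid-poor
angiomyolipoma, leiomyoma) from renal cell carcinoma poorly, so many benign
masses are resected unnecessarily. Quantitative texture features extracted
from routine portal-venous-phase CT carry additional signal — but radiomic
feature tables are small (n ≈ 85), imbalanced (~40% benign), heavily
redundant, and confounded by the scanner and reconstruction settings that
produced the images. This package implements a pipeline built specifically
around those four problems. It consumes patient × feature tables (it does
not segment images or extract features), and ships a synthetic cohort
generator that emulates the study conditions so every stage is testable
without patient data.

## Method

For a training cohort with features *x₁…x_p*, binary outcome *y*
(malignant = 1) and per-patient acquisition metadata:

1. **Redundancy elimination** — drop one feature of every pair with
   |Pearson r| > 0.99 (lexicographically later name dropped).
2. **Standardization** — z-score with training-subset mean/sd; parameters
   are transferred unchanged to validation/test data, never refitted.
3. **Class balancing** — Random Walk Oversampling (RWO) of the minority
   class: a synthetic row perturbs a real row by
   x′ⱼ = xⱼ − (σⱼ/√m)·rⱼ, rⱼ ~ N(0,1), preserving the class mean and
   inflating the variance only by (1 + 1/m). Training subsets only.
4. **Reproducibility chain** — ordered per-feature screens against
   acquisition parameters: Kruskal–Wallis vs scanner model, then vs
   convolution kernel (remove if p < 0.05); Spearman vs pixel spacing,
   slice thickness, tube voltage (remove if |ρ| > 0.75). A feature is
   removed at the first failing test.
5. **Stability feature selection** — a 100-round Monte-Carlo CV: each round
   redraws an 80/20 stratified subset, reruns steps 1–4 on the 80% side and
   applies a two-sided Mann–Whitney filter at p < 0.05. A feature scores a
   point per selected round; the **signature is the top-10 cumulative
   scorers**.
6. **Classification** — PCA or ICA to d ∈ {2, 3} components followed by a
   k-NN vote (Euclidean distance, odd k) on the balanced reference set; a
   second 100-round MCCV tunes (reduction, d, k) by mean validation
   minority-class F1 and evaluates the frozen final model on the untouched
   test set each round. Reported metrics: ROC-AUC, accuracy, sensitivity,
   specificity, PPV, NPV (malignant positive) and F1 (benign positive).

## Worked example

```python
from srmrad import (GeneratorConfig, SplitSpec, generate_cohort, ground_truth,
                    run_fs_mccv, select_signature, stratified_split)

cohort = generate_cohort(GeneratorConfig(seed=0))   # 85 patients, 107 features
train, test = stratified_split(cohort, SplitSpec(0.2, True, 0))
board = run_fs_mccv(train, rounds=25, base_seed=100)
for name in select_signature(board, 10):
    print(name, int(board.scores[name]), ground_truth(cohort)[name])
```

prints (abridged):

```
rf_044  25  informative
rf_071  25  informative
rf_034  25  informative
rf_053  25  informative
rf_051  24  informative
rf_057  18  redundant_anchor
rf_018  15  noise
...
```

All 5 planted class-informative features top the scoreboard with
near-perfect stability; the remaining signature slots are filled by the
luckiest noise features — an honest picture of what stability selection on
a single small cohort can and cannot guarantee. Training the tuned
PCA(2)+7-NN model on this signature gives a mean test ROC-AUC ≈ 0.93 at the
default planted effect size (1.5 sd).

The `examples/` directory has one narrative script per capability
(simulation, feature screening, signature selection, tuning/training, full
pipeline), and `srmrad --help` exposes the same steps as CLI subcommands
(`simulate`, `split`, `select-features`, `tune`, `train`, `report`,
`run-all`).

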