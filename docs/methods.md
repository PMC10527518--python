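# Methods

This note documents the statistical model behind `srmrad`, the choices the
package makes where the method leaves room, and what its synthetic-data
tests do and do not demonstrate.

## The estimation problem

The target of inference is a short, scanner-robust radiomic signature that
discriminates benign from malignant small renal masses on
portal-venous-phase CT, together with an honest estimate of its
out-of-sample performance. The setting is hostile to standard model
selection: n ≈ 85 patients against ~107 features, ~40% minority class,
strong feature collinearity (texture-feature families are near-duplicates),
and batch structure induced by three scanner models with nested
reconstruction kernels. The pipeline answers with (a) hard filters for
redundancy and scanner dependence, (b) univariable stability selection
under Monte-Carlo cross-validation (MCCV), and (c) a deliberately
low-capacity classifier (2–3 component linear reduction + kNN).

## Data model and splitting

A `Cohort` is a validated patient × feature table with a binary outcome,
optional histotype, and five acquisition parameters per patient (scanner
model, convolution kernel, pixel spacing, slice thickness, tube voltage).
Missing feature values are a hard error: no imputation is defined anywhere
in the method, and silently imputing would interact badly with the rank
tests.

Stratified splits allocate per-class test counts by largest-remainder
apportionment of `round(n·fraction)`. With 51/34 patients at fraction 0.2
this gives the canonical 17-patient test set (10 malignant / 7 benign).
The same splitter drives the outer train/test split and every inner 80/20
MCCV round.

## Preprocessing

**Redundancy.** Pearson |r| > 0.99 defines a redundant pair; the absolute
value is used because an anti-correlated duplicate carries the same
information. The eliminator scans feature names lexicographically and drops
the later name of each offending pair, which makes the survivor set
deterministic and invariant to row order. Constant columns are removed here
(with a distinct report entry) rather than crashing the z-score later —
at MCCV-subset sizes a discretized feature can easily become constant.

**Standardization.** Per-feature mean and sample sd (n−1) are fitted on the
training subset of the moment and applied unchanged everywhere else. The
test suite verifies transfer by injecting a known shift and asserting it
appears as shift/sd rather than being re-absorbed.

**Random Walk Oversampling.** Minority rows are oversampled by
x′ⱼ = xⱼ − (σⱼ/√m)·rⱼ with σⱼ the population-form (denominator m) minority
sd. First two moments: E[x′] equals the minority mean and
Var[x′] = σ²(1 + 1/m), both asserted against closed form by simulation.
Synthetic rows are flagged, inherit their source row's metadata and
histotype, and exist only inside training subsets. Because their metadata
is copied rather than acquired, the reproducibility chain always runs on
the real rows only.

## Reproducibility chain

Five tests in fixed order — scanner model, kernel (Kruskal–Wallis,
p < 0.05), then pixel spacing, thickness, voltage (Spearman,
|ρ| > 0.75) — with removal at the first failure, so each removal is
attributed to exactly one parameter. No multiplicity correction is applied:
the raw thresholds are the method's stated operating point, and the ~5%
per-categorical-test false-removal rate is part of its behavior (verified
by calibration test). The chain is recomputed inside every MCCV round by
default (a one-shot global mode exists), which is what produces the
round-to-round spread in the number of features reaching selection.
Whether a categorical parameter has collapsed to a single level in a small
subset is checked per round; the test is then skipped with a recorded
warning. Continuous parameters are tested on raw values, unbinned.

The chain's rank statistics are computed by a vectorized implementation
(all features at once); unit tests pin it feature-by-feature to the scalar
scipy-backed operations.

## Stability selection

Each round draws an 80/20 stratified subset of the training set, applies
the full preprocessing stack to the 80% side, and tests every surviving
feature with a two-sided Mann–Whitney U (exact for combined n ≤ 20 without
ties, tie-corrected normal approximation otherwise). The Mann–Whitney input
is the RWO-balanced subset, matching the stated preprocessing order; an
option computes it on the unbalanced subset for sensitivity analysis.
A feature eliminated by preprocessing in a round scores 0 for that round
(cumulative-score semantics — the alternative, excluding such rounds from
the denominator, would reward fragile features). The signature is the
top-10 by cumulative score, ties broken by ascending mean Mann–Whitney p,
then name.

**A caveat the tests make explicit:** the cumulative score measures
selection *stability on one fixed training set*, not cross-dataset
significance. MCCV rounds are resamples of the same patients, so a noise
feature whose sample association with the outcome is lucky in that training
set is re-selected in most rounds; on label-null cohorts the maximum
cumulative score routinely reaches 0.6–1.0 of the rounds. High scores
identify reliably-selected features; they are not evidence of signal by
themselves — that evidence comes from held-out performance.

## Classifier and tuning

PCA (full SVD) or FastICA reduces the standardized signature to d ∈ {2, 3}
components; components are ordered by explained variance and sign-fixed
(largest-magnitude loading positive) so both reductions are deterministic,
ICA additionally under a fixed seed. The kNN vote uses Euclidean distance
in component space with odd k (no vote ties); exact distance ties are
broken by reference insertion order via a stable sort. The malignancy score
is the malignant fraction among the k neighbors.

Metric conventions: sensitivity/specificity/PPV/NPV take malignant as
positive; F1 takes the minority benign class as positive. ROC-AUC is the
normalized Mann–Whitney statistic of the scores. PPV/NPV are undefined
(NaN, NaN-aware aggregation) in the rare round where no patient is
predicted in a class.

Tuning evaluates every (reduction, d, k) grid point — default k ∈
{3,5,7,9,11,13,15} — on identical per-round splits (shared seeds, paired
comparison) and maximizes mean validation F1; ties prefer smaller d, then
smaller k, then PCA. Test metrics are computed only for the final
configuration. The default `ModelConfig` is PCA, d = 2, k = 7, the method's
tuned operating point.

## Synthetic cohort generator

The generator is the package's stand-in for patient data and encodes the
study conditions as defaults: 85 patients in six histotypes
(37 clear-cell + 7 chromophobe + 7 papillary RCC; 25 oncocytoma + 7
lipid-poor AML + 2 leiomyoma), 107 features, metadata uniform over the
acquisition ranges (pixel spacing 0.61–0.98 mm, thickness 1.5–2.5 mm,
100–130 kVp), three scanner models with kernels nested per scanner
(B31s/B40s; B20f/B30f; Br32f). Feature structure, scattered over a seeded
permutation of positions so order carries no information:

* 5 informative features: +effect_size·y, default 1.5 sd — large enough
  that a rank test at n = 85 has essentially full power, small enough that
  per-round selection is not trivially saturated;
* 24 scanner-affected features: +batch_shift·(scanner index), default
  1 sd per step — chosen so that test n.1 removes roughly 30% of the
  non-redundant features, the magnitude the method reports;
* 9 blocks of 4 near-duplicates (anchor + jitter, sd 0.05 → pairwise
  r ≈ 0.999), putting ~25% of features above the redundancy threshold;
* remaining 42 features are N(0,1) noise.

Additive batch effects (not multiplicative) are the simplest mechanism the
Kruskal–Wallis screen detects; continuous metadata is independent of the
outcome by default so reproducibility filtering and class signal stay
orthogonal. What the generator does **not** emulate: the joint correlation
structure of real texture features, non-Gaussian marginals, and any
coupling between histotype and acquisition. Passing tests therefore
demonstrate the pipeline's mechanics and calibration, not clinical
performance.

## Problem sizes and numerical choices

MCCV stages run at 100 rounds by default; the test suite and the
acceptance script run them at 25 rounds, comparing scores as fractions of
the round count (the per-round mechanics are unchanged). The
label-permutation null averages 5 independent permutations because a single
17-patient test set makes one permutation's mean AUC too noisy (null sd
≈ 0.15) for a meaningful chance band. Sub-seeds are derived arithmetically
from one base seed; every artifact-writing path serializes with sorted keys
and no timestamps, so a manifest replay is byte-identical.

## Known limitations

* The signature's content on null data is dominated by dataset luck (see
  stability caveat above); only held-out metrics are protective.
* Feature count is data-driven; nothing assumes exactly 107 or 108
  features.
* ICA convergence warnings can occur on near-Gaussian subsets; the fixed
  seed and variance-ordering make results reproducible regardless.
* No harmonization (e.g. location/scale batch adjustment) is offered:
  non-reproducible features are removed, not corrected.
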