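"""Second MCCV step: PCA/ICA dimensionality reduction + kNN classification.

The classifier operates on the fixed 10-feature signature.  Per round an
80/20 stratified subset of the training set is drawn; the z-score
parameters, the RWO-balanced reference set and the reduction transform are
fitted on the 80% part only and applied unchanged to the round's validation
subset and to the fixed test set.  Hyperparameters (reduction technique,
number of components d in {2, 3}, odd neighbor count k) are tuned by the
mean minority-class F1 on the validation subsets, with per-round seeds
shared across the grid so configurations are compared on identical splits.

Metric conventions (the only assignment consistent with the study's
prevalence arithmetic): sensitivity/specificity/PPV/NPV treat malignant as
the positive class; the F1 score treats the minority — benign — class as
positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA, FastICA
from sklearn.metrics import roc_auc_score

from .cohort import Cohort, SplitSpec, stratified_split
from .preprocess import (
    StandardizationParams,
    apply_standardizer,
    balance_training_subset,
    fit_standardizer,
)

METRIC_NAMES = ("roc_auc", "accuracy", "sensitivity", "specificity", "ppv", "npv", "f1_minority")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Reduction technique + component count d + neighbor count k.

    d is constrained to {2, 3} to keep the component space plottable and to
    sidestep the curse of dimensionality at n = 85; k must be odd so the
    majority vote of a binary kNN can never tie.  The default is the tuned
    operating point of the method: PCA, d = 2, k = 7.
    """

    reduction: str = "pca"
    d: int = 2
    k: int = 7

    def __post_init__(self) -> None:
        if self.reduction not in ("pca", "ica"):
            raise ModelError(f"reduction must be 'pca' or 'ica', got {self.reduction!r}")
        if self.d not in (2, 3):
            raise ModelError(f"d must be 2 or 3, got {self.d}")
        if self.k < 3 or self.k % 2 == 0:
            raise ModelError(f"k must be an odd integer >= 3, got {self.k}")

    def to_dict(self) -> dict:
        return {"reduction": self.reduction, "d": self.d, "k": self.k}


def default_grid(
    reductions=("pca", "ica"), dims=(2, 3), neighbors=(3, 5, 7, 9, 11, 13, 15)
) -> list[ModelConfig]:
    return [ModelConfig(r, d, k) for r, d, k in product(reductions, dims, neighbors)]


# ---------------------------------------------------------------------------
# Dimensionality reduction
# ---------------------------------------------------------------------------


@dataclass
class Reduction:
    """Fitted linear projection: transform(X) = (X - mean) @ weights.T.

    Components are ordered by decreasing explained variance and sign-fixed
    so each component's largest-magnitude weight is positive, making both
    PCA and ICA outputs deterministic and comparable across rounds.
    """

    kind: str
    mean_: np.ndarray
    weights_: np.ndarray  # (d, p)
    component_variance_: np.ndarray

    @property
    def d(self) -> int:
        return self.weights_.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.weights_.T


def _sign_fix(weights: np.ndarray) -> np.ndarray:
    out = weights.copy()
    for i, row in enumerate(out):
        if row[np.argmax(np.abs(row))] < 0:
            out[i] = -row
    return out


def fit_reduction(features: np.ndarray, config: ModelConfig, seed: int = 0) -> Reduction:
    """Fit PCA or FastICA with ``d`` components on standardized features."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] <= config.d:
        raise ModelError(f"need more than d={config.d} rows, got {X.shape[0]}")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if config.d > rank:
        raise ModelError(f"d={config.d} exceeds the rank ({rank}) of the centered data")
    if config.reduction == "pca":
        pca = PCA(n_components=config.d, svd_solver="full").fit(X)
        weights = _sign_fix(pca.components_)
        return Reduction("pca", pca.mean_.copy(), weights, pca.explained_variance_.copy())
    ica = FastICA(
        n_components=config.d,
        whiten="unit-variance",
        random_state=int(seed) % (2**31),
        max_iter=2000,
        tol=1e-5,
    ).fit(X)
    weights = ica.components_  # unmixing; transform is (X - mean) @ W.T
    # order by the variance each component explains in X (norm of its mixing column)
    explained = np.square(ica.mixing_).sum(axis=0)
    order = np.argsort(-explained, kind="stable")
    return Reduction("ica", ica.mean_.copy(), _sign_fix(weights[order]), explained[order])


# ---------------------------------------------------------------------------
# kNN in component space
# ---------------------------------------------------------------------------


def knn_score(
    reference_points: np.ndarray,
    reference_labels: np.ndarray,
    queries: np.ndarray,
    k: int,
) -> np.ndarray:
    """Malignancy score: fraction of the k Euclidean-nearest references labeled 1.

    Exact distance ties are broken by reference insertion order (stable sort).
    """
    refs = np.asarray(reference_points, dtype=float)
    labels = np.asarray(reference_labels)
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if k > len(refs):
        raise ModelError(f"k={k} exceeds the {len(refs)} reference points")
    d2 = np.square(queries[:, None, :] - refs[None, :, :]).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")
    return labels[order[:, :k]].mean(axis=1)


@dataclass
class TrainedModel:
    """Frozen preprocessing + reduction + kNN reference set for one round."""

    standardizer: StandardizationParams
    signature: list[str]
    reduction: Reduction
    reference_points: np.ndarray
    reference_labels: np.ndarray
    config: ModelConfig

    def project(self, features: pd.DataFrame) -> np.ndarray:
        z = apply_standardizer(self.standardizer, features[self.signature])
        return self.reduction.transform(z.to_numpy(dtype=float))

    def predict(self, features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Malignancy scores in [0, 1] and hard labels (score > 0.5)."""
        scores = knn_score(
            self.reference_points, self.reference_labels, self.project(features), self.config.k
        )
        return scores, (scores > 0.5).astype(int)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def evaluate_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Binary performance metrics from malignancy scores.

    ROC-AUC is the normalized Mann-Whitney statistic of the scores (ties
    count one half).  PPV/NPV are NaN when no patient is predicted in the
    respective class; aggregation uses NaN-aware means.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ModelError("both classes must be present to evaluate metrics")
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    prec_benign = ratio(tn, tn + fn)
    rec_benign = ratio(tn, tn + fp)
    if np.isnan(prec_benign) or (prec_benign + rec_benign) == 0:
        f1 = 0.0
    else:
        f1 = 2 * prec_benign * rec_benign / (prec_benign + rec_benign)
    return {
        "roc_auc": float(roc_auc_score(labels, scores)),
        "accuracy": (tp + tn) / len(labels),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "f1_minority": f1,
    }


# ---------------------------------------------------------------------------
# Training MCCV and tuning
# ---------------------------------------------------------------------------


@dataclass
class PerformanceSummary:
    """Per-round validation/test metrics and their mean +/- sd over rounds."""

    config: ModelConfig
    validation_rounds: pd.DataFrame
    test_rounds: pd.DataFrame | None = None
    degenerate_sd: bool = False  # single round: sd reported as 0 by convention

    def _agg(self, df: pd.DataFrame) -> pd.DataFrame:
        mean = df.mean(skipna=True)
        sd = df.std(ddof=1, skipna=True)
        if len(df) == 1:
            sd = sd.fillna(0.0)
        return pd.DataFrame({"mean": mean, "sd": sd})

    def summary(self) -> pd.DataFrame:
        out = self._agg(self.validation_rounds)
        out.columns = pd.MultiIndex.from_product([["validation"], out.columns])
        if self.test_rounds is not None:
            t = self._agg(self.test_rounds)
            t.columns = pd.MultiIndex.from_product([["test"], t.columns])
            out = pd.concat([out, t], axis=1)
        return out

    @property
    def mean_validation_f1(self) -> float:
        return float(np.nanmean(self.validation_rounds["f1_minority"]))

    def to_dict(self) -> dict:
        def clean(df: pd.DataFrame) -> dict:
            agg = self._agg(df)
            return {
                m: {"mean": round(float(agg.loc[m, "mean"]), 10),
                    "sd": round(float(agg.loc[m, "sd"]), 10)}
                for m in df.columns
            }

        out = {"config": self.config.to_dict(), "validation": clean(self.validation_rounds)}
        if self.test_rounds is not None:
            out["test"] = clean(self.test_rounds)
        return out


def train_round(
    training_set: Cohort, signature: list[str], config: ModelConfig, seed: int
) -> tuple[TrainedModel, Cohort]:
    """Fit one round's model on an inner 80% subset; return it and the 20%."""
    sub = training_set.select_features(signature)
    work, held_out = stratified_split(sub, SplitSpec(0.2, True, seed))
    params = fit_standardizer(work.features)
    work_z = work.with_features(apply_standardizer(params, work.features))
    balanced = balance_training_subset(work_z, seed=seed)
    red = fit_reduction(balanced.features.to_numpy(dtype=float), config, seed=seed)
    model = TrainedModel(
        standardizer=params,
        signature=list(signature),
        reduction=red,
        reference_points=red.transform(balanced.features.to_numpy(dtype=float)),
        reference_labels=balanced.labels.to_numpy(),
        config=config,
    )
    return model, held_out


def run_training_mccv(
    training_set: Cohort,
    signature: list[str],
    config: ModelConfig,
    rounds: int = 100,
    base_seed: int = 0,
    test_set: Cohort | None = None,
) -> PerformanceSummary:
    """Train/evaluate over MCCV rounds with fixed hyperparameters.

    Per-round seeds are base_seed+1..base_seed+rounds.  The test set, when
    given, is evaluated with each round's frozen model; it never influences
    fitting.
    """
    if rounds < 1:
        raise ModelError("rounds must be >= 1")
    missing = [f for f in signature if f not in training_set.feature_names]
    if missing:
        raise ModelError(f"signature features absent from the training set: {missing}")
    val_rows, test_rows = [], []
    for r in range(1, rounds + 1):
        model, val = train_round(training_set, signature, config, base_seed + r)
        scores, _pred = model.predict(val.features)
        val_rows.append(evaluate_metrics(scores, val.labels.to_numpy()))
        if test_set is not None:
            t_scores, _ = model.predict(test_set.features[signature])
            test_rows.append(evaluate_metrics(t_scores, test_set.labels.to_numpy()))
    return PerformanceSummary(
        config=config,
        validation_rounds=pd.DataFrame(val_rows, columns=list(METRIC_NAMES)),
        test_rounds=pd.DataFrame(test_rows, columns=list(METRIC_NAMES)) if test_set is not None else None,
        degenerate_sd=rounds == 1,
    )


@dataclass
class TuningResult:
    best: ModelConfig
    curve: pd.DataFrame  # one row per grid point: reduction, d, k, mean/sd val F1


def tune(
    training_set: Cohort,
    signature: list[str],
    grid: list[ModelConfig] | None = None,
    rounds: int = 100,
    base_seed: int = 0,
) -> TuningResult:
    """Grid search maximizing mean validation minority-F1, paired by seed.

    Every configuration sees the identical per-round splits (common seeds),
    so the comparison is paired.  Ties prefer smaller d, then smaller k,
    then PCA over ICA.  Test data plays no role here.
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ModelError("empty tuning grid")
    rows = []
    for cfg in grid:
        perf = run_training_mccv(training_set, signature, cfg, rounds, base_seed, test_set=None)
        f1 = perf.validation_rounds["f1_minority"]
        rows.append(
            {
                "reduction": cfg.reduction,
                "d": cfg.d,
                "k": cfg.k,
                "mean_val_f1": float(np.nanmean(f1)),
                "sd_val_f1": float(np.nanstd(f1, ddof=1)) if rounds > 1 else 0.0,
            }
        )
    curve = pd.DataFrame(rows)
    ranked = sorted(
        range(len(grid)),
        key=lambda i: (
            -rows[i]["mean_val_f1"],
            grid[i].d,
            grid[i].k,
            0 if grid[i].reduction == "pca" else 1,
        ),
    )
    return TuningResult(best=grid[ranked[0]], curve=curve)
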