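"""Preprocessing: redundancy elimination, z-scoring with train-to-unseen
transfer, and Random Walk Oversampling (RWO) of the minority class.

All operations are pure functions of their inputs plus a seed, and are
always fitted on a training subset only; the fitted parameters are then
applied unchanged to validation/test data (never refitted), which is the
leakage-control discipline the whole pipeline rests on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Redundancy elimination
# ---------------------------------------------------------------------------


@dataclass
class RedundancyReport:
    """Which features were dropped as redundant, and why.

    ``dropped`` records (dropped_feature, retained_partner, r) triples;
    zero-variance columns appear with partner None and r None.
    """

    threshold: float
    dropped: list[tuple[str, str | None, float | None]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    @property
    def dropped_names(self) -> list[str]:
        return [d[0] for d in self.dropped]

    def to_json(self) -> str:
        return json.dumps(
            {
                "threshold": self.threshold,
                "dropped": [
                    {"feature": f, "retained_partner": p, "r": r}
                    for f, p, r in self.dropped
                ],
                "retained": self.retained,
            },
            indent=2,
            sort_keys=True,
        )


def eliminate_redundant(
    features: pd.DataFrame, threshold: float = 0.99
) -> tuple[pd.DataFrame, RedundancyReport]:
    """Greedily drop one of every feature pair with |Pearson r| > threshold.

    Features are scanned in lexicographic name order; for an offending pair
    the lexicographically later name is dropped, so the result does not
    depend on row or column order.  Zero-variance columns are removed first
    with a distinct report entry (r undefined).  After elimination no
    surviving pair exceeds the threshold.
    """
    if len(features) < 2:
        raise PreprocessError("need at least 2 rows to compute correlations")
    if not 0.0 < threshold < 1.0:
        raise PreprocessError(f"threshold must be in (0, 1), got {threshold}")
    report = RedundancyReport(threshold=threshold)

    constant = features.min() == features.max()  # exact, unlike sd == 0
    zero_var = sorted(constant.index[constant])
    for name in zero_var:
        report.dropped.append((name, None, None))
    live = [c for c in features.columns if c not in set(zero_var)]

    if live:
        order = sorted(live)
        corr = np.corrcoef(features[order].to_numpy(dtype=float), rowvar=False)
        corr = np.atleast_2d(corr)
        dropped: set[str] = set()
        for i, a in enumerate(order):
            if a in dropped:
                continue
            for j in range(i + 1, len(order)):
                b = order[j]
                if b in dropped:
                    continue
                r = float(corr[i, j])
                if abs(r) > threshold:
                    dropped.add(b)
                    report.dropped.append((b, a, r))
        keep = [c for c in features.columns if c in set(live) - dropped]
    else:
        keep = []
    report.retained = keep
    return features[keep], report


# ---------------------------------------------------------------------------
# Standardization (z-score) with explicit train -> unseen transfer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature mean/sd learned on a training subset (sample sd, n-1)."""

    mean: pd.Series
    sd: pd.Series
    fitted_on: str = "training"

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise PreprocessError("mean and sd cover different features")
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise PreprocessError(f"non-positive sd for features {bad}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.mean.index)


def fit_standardizer(features: pd.DataFrame, fitted_on: str = "training") -> StandardizationParams:
    if len(features) < 2:
        raise PreprocessError("need at least 2 rows to fit a standardizer")
    constant = features.min() == features.max()
    if constant.any():
        bad = list(constant.index[constant])
        raise PreprocessError(
            f"zero-variance features {bad}: remove them with eliminate_redundant first"
        )
    return StandardizationParams(
        mean=features.mean(), sd=features.std(ddof=1), fitted_on=fitted_on
    )


def apply_standardizer(params: StandardizationParams, features: pd.DataFrame) -> pd.DataFrame:
    """(x - mean)/sd with the stored training parameters; never refits."""
    unknown = [c for c in features.columns if c not in set(params.feature_names)]
    if unknown:
        raise PreprocessError(f"features not covered by the standardizer: {unknown}")
    cols = list(features.columns)
    return (features - params.mean[cols]) / params.sd[cols]


# ---------------------------------------------------------------------------
# Random Walk Oversampling
# ---------------------------------------------------------------------------


def rwo_oversample(
    minority: pd.DataFrame, n_synthetic: int, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthesize minority-class rows by short Gaussian random-walk steps.

    Each synthetic row starts from a uniformly chosen minority row ``x`` and
    perturbs every feature j as ``x_j - (sigma_j / sqrt(m)) * r_j`` with
    ``r_j ~ N(0,1)``, ``m`` the minority size and ``sigma_j`` the minority
    sd of feature j (population form, denominator m).  The construction
    preserves the minority mean and inflates the variance only by a factor
    ``1 + 1/m``, which is what makes RWO attractive on tiny medical cohorts.

    Returns the synthetic rows and the positional indices of their source
    rows (needed to carry acquisition metadata along).
    """
    m = len(minority)
    if m < 2:
        raise PreprocessError("minority class needs >= 2 rows (sd undefined otherwise)")
    if n_synthetic < 0:
        raise PreprocessError("n_synthetic must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = minority.to_numpy(dtype=float)
    sigma = X.std(axis=0, ddof=0)
    src = rng.integers(0, m, size=n_synthetic)
    steps = rng.standard_normal((n_synthetic, X.shape[1]))
    synth = X[src] - (sigma / np.sqrt(m)) * steps
    out = pd.DataFrame(synth, columns=minority.columns)
    return out, src


def balance_training_subset(cohort: Cohort, seed: int = 0) -> Cohort:
    """Append RWO rows for the minority class until class counts are equal.

    Synthetic rows are flagged via ``is_synthetic`` and inherit the
    acquisition metadata and histotype of their source patient; they must
    never be used for reproducibility testing or enter validation/test data.
    Already-balanced input is returned unchanged.
    """
    counts = cohort.label_counts()
    if len(counts) < 2:
        raise PreprocessError("both outcome classes must be present to balance")
    minority_label = min(counts, key=lambda c: (counts[c], c))
    majority = max(counts.values())
    n_needed = majority - counts[minority_label]
    if n_needed == 0:
        return cohort

    mask = cohort.labels == minority_label
    minority_ids = list(cohort.labels.index[mask])
    synth, src = rwo_oversample(
        cohort.features.loc[minority_ids], n_needed, np.random.default_rng(seed)
    )
    src_ids = [minority_ids[i] for i in src]
    new_ids = [f"{sid}__syn{i:03d}" for i, sid in enumerate(src_ids)]
    synth.index = pd.Index(new_ids, name=cohort.features.index.name)

    feats = pd.concat([cohort.features, synth])
    labels = pd.concat(
        [cohort.labels, pd.Series(minority_label, index=synth.index, name="label")]
    )
    meta = pd.concat([cohort.metadata, cohort.metadata.loc[src_ids].set_index(synth.index)])
    histo = None
    if cohort.histotype is not None:
        histo = pd.concat(
            [cohort.histotype, cohort.histotype.loc[src_ids].set_axis(synth.index)]
        )
    flags = pd.concat(
        [cohort.is_synthetic, pd.Series(True, index=synth.index)]
    )
    return Cohort(
        features=feats,
        labels=labels,
        metadata=meta,
        histotype=histo,
        is_synthetic=flags,
        feature_roles=cohort.feature_roles,
    )
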