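"""Acquisition-parameter reproducibility screening.

Radiomic features that track the scanner or reconstruction settings rather
than the tumor are useless across imaging platforms.  Each feature is run
through an ordered chain of five association tests against the acquisition
metadata:

    n.1  scanner model        Kruskal-Wallis, remove if p < alpha
    n.2  convolution kernel   Kruskal-Wallis, remove if p < alpha
    n.3  pixel spacing        Spearman, remove if |rho| > rho_threshold
    n.4  slice thickness      Spearman, remove if |rho| > rho_threshold
    n.5  tube voltage         Spearman, remove if |rho| > rho_threshold

A feature is removed at the FIRST failing test and not tested further, so
the attribution of a removal respects the chain order.  No multiplicity
correction is applied across features or tests: the raw thresholds are the
method's stated operating point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort


class ReproducibilityError(ValueError):
    pass


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    Degenerate all-tied input returns H = 0, p = 1 (no rank variation).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ReproducibilityError("Kruskal-Wallis needs at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ReproducibilityError("every group needs at least one observation")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


class SpearmanResult(NamedTuple):
    rho: float
    defined: bool  # False when either vector is constant (rho undefined, reported 0)


def spearman_rho(values, covariate) -> SpearmanResult:
    """Spearman rank correlation (Pearson on tie-aware mid-ranks)."""
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if values.shape != covariate.shape or len(values) < 3:
        raise ReproducibilityError("need equal-length vectors of length >= 3")
    if np.all(covariate == covariate[0]) or np.all(values == values[0]):
        return SpearmanResult(0.0, False)
    rho = stats.spearmanr(values, covariate).statistic
    return SpearmanResult(float(rho), True)


# ---------------------------------------------------------------------------
# Vectorized internals: the chain screens ~100 features per MCCV round, so the
# rank statistics are computed for all feature columns at once.  They must
# agree with the scalar operations above (asserted in the test suite).
# ---------------------------------------------------------------------------


def _tie_sums(X: np.ndarray) -> np.ndarray:
    """Sum of (t^3 - t) over tie groups, per column."""
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        counts = np.unique(X[:, j], return_counts=True)[1]
        out[j] = float(np.sum(counts**3 - counts))
    return out


def _kw_all_features(X: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tie-corrected Kruskal-Wallis H and chi-square p, per feature column."""
    n, p = X.shape
    levels = pd.unique(groups)
    ranks = stats.rankdata(X, axis=0)
    h = np.zeros(p)
    for g in levels:
        m = groups == g
        h += np.square(ranks[m].sum(axis=0)) / int(m.sum())
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_sums(X) / (n**3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(correction > 0, h / correction, 0.0)
    h = np.where(np.abs(h) < 1e-12, 0.0, h)  # all-tied columns
    pval = np.where(h == 0.0, 1.0, stats.chi2.sf(h, len(levels) - 1))
    return h, pval


def _spearman_all_features(X: np.ndarray, covariate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho per column (Pearson on mid-ranks); flags undefined cases."""
    n = X.shape[0]
    rx = stats.rankdata(X, axis=0)
    rc = stats.rankdata(covariate)
    rx_c = rx - rx.mean(axis=0)
    rc_c = rc - rc.mean()
    denom = np.sqrt(np.square(rx_c).sum(axis=0) * np.square(rc_c).sum())
    defined = denom > 0
    rho = np.zeros(X.shape[1])
    np.divide(rx_c.T @ rc_c, denom, out=rho, where=defined)
    return rho, defined


#: (report label, metadata column, test kind) in fixed chain order
CHAIN = (
    ("scanner_model", "scanner_model", "kw"),
    ("convolution_kernel", "convolution_kernel", "kw"),
    ("pixel_spacing", "pixel_spacing_mm", "spearman"),
    ("slice_thickness", "slice_thickness_mm", "spearman"),
    ("tube_voltage", "tube_voltage_kvp", "spearman"),
)
CHAIN_ORDER = tuple(label for label, _, _ in CHAIN)


@dataclass
class ReproducibilityReport:
    """Per-feature outcome of the five-test chain.

    ``rows`` has one entry per input feature: kept flag, removing test
    (or "none"), the statistic (H or rho) and the decision value (p or rho)
    at the point the chain stopped.  ``warnings`` records skipped tests
    (e.g. a categorical parameter with a single level in this subset).
    """

    alpha: float
    rho_threshold: float
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    warnings: list[str] = field(default_factory=list)

    @property
    def kept(self) -> list[str]:
        return list(self.rows.index[self.rows["kept"]])

    def removal_counts(self) -> dict[str, int]:
        out = {label: 0 for label in CHAIN_ORDER}
        for label, cnt in self.rows["removed_by"].value_counts().items():
            if label != "none":
                out[label] = int(cnt)
        return out

    def removal_summary(self) -> pd.DataFrame:
        """Removal count and percentage of input features, per chain test."""
        counts = self.removal_counts()
        n = len(self.rows)
        return pd.DataFrame(
            {
                "removed": [counts[t] for t in CHAIN_ORDER],
                "percent": [100.0 * counts[t] / n if n else 0.0 for t in CHAIN_ORDER],
            },
            index=pd.Index(CHAIN_ORDER, name="test"),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "rho_threshold": self.rho_threshold,
                "features": {
                    name: {
                        "kept": bool(row["kept"]),
                        "removed_by": row["removed_by"],
                        "statistic": None if pd.isna(row["statistic"]) else float(row["statistic"]),
                        "value": None if pd.isna(row["value"]) else float(row["value"]),
                    }
                    for name, row in self.rows.iterrows()
                },
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
        )


def apply_reproducibility_chain(
    cohort: Cohort,
    alpha: float = 0.05,
    rho_threshold: float = 0.75,
    features: list[str] | None = None,
) -> tuple[list[str], ReproducibilityReport]:
    """Run the ordered five-test chain on the cohort's (real) training rows.

    Synthetic oversampled rows carry copied, not acquired, metadata and are
    excluded.  A categorical test whose parameter has a single level in this
    subset is skipped with a recorded warning.  Returns surviving feature
    names (input order) and the full report.
    """
    real = cohort.real_rows()
    names = list(features) if features is not None else cohort.feature_names
    report = ReproducibilityReport(alpha=alpha, rho_threshold=rho_threshold)

    active: list[tuple[str, str, str]] = []
    for label, col, kind in CHAIN:
        if kind == "kw" and real.metadata[col].nunique() < 2:
            report.warnings.append(
                f"test {label} skipped: parameter has a single level in this subset"
            )
            continue
        active.append((label, col, kind))

    X = real.features[names].to_numpy(dtype=float)
    # per active test: (fails, statistic, value) arrays over features
    outcomes = []
    for label, col, kind in active:
        if kind == "kw":
            h, p = _kw_all_features(X, real.metadata[col].to_numpy())
            outcomes.append((label, p < alpha, h, p))
        else:
            rho, defined = _spearman_all_features(
                X, real.metadata[col].to_numpy(dtype=float)
            )
            outcomes.append((label, defined & (np.abs(rho) > rho_threshold), rho, rho))

    records = []
    for i, name in enumerate(names):
        kept, removed_by, statistic, value = True, "none", np.nan, np.nan
        for label, fails, stat_arr, val_arr in outcomes:
            if fails[i]:
                kept, removed_by = False, label
                statistic, value = float(stat_arr[i]), float(val_arr[i])
                break
        records.append((name, kept, removed_by, statistic, value))

    report.rows = pd.DataFrame(
        records, columns=["feature", "kept", "removed_by", "statistic", "value"]
    ).set_index("feature")
    return report.kept, report
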