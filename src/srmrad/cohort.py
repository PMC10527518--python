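"""Cohort data model, delimited-table I/O and stratified splitting.

A cohort is a patient x radiomic-feature table with a binary outcome label
(malignant = 1, benign = 0), an optional histotype, and per-patient CT
acquisition metadata (scanner model, convolution kernel, pixel spacing,
slice thickness, tube voltage).  All downstream stages operate on this
container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LABEL_BENIGN = 0
LABEL_MALIGNANT = 1

#: acquisition metadata columns, in reproducibility-chain order
CATEGORICAL_PARAMETERS = ("scanner_model", "convolution_kernel")
CONTINUOUS_PARAMETERS = ("pixel_spacing_mm", "slice_thickness_mm", "tube_voltage_kvp")
METADATA_COLUMNS = CATEGORICAL_PARAMETERS + CONTINUOUS_PARAMETERS

RESERVED_COLUMNS = ("patient_id", "label", "histotype", "is_synthetic") + METADATA_COLUMNS


class CohortError(ValueError):
    """Base class for cohort validation problems."""


class SchemaError(CohortError):
    """A required column is missing or misnamed."""


class ParseError(CohortError):
    """A feature cell could not be interpreted as a number."""


@dataclass(frozen=True)
class SplitSpec:
    """How to split a cohort into train/test (or the 80/20 MCCV subsets)."""

    test_fraction: float = 0.2
    stratify_on_label: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise CohortError(
                f"test_fraction must lie strictly in (0, 1), got {self.test_fraction}"
            )


@dataclass
class Cohort:
    """Validated patient x feature table with labels and acquisition metadata.

    All frames/series are indexed by patient id.  ``is_synthetic`` marks rows
    appended by minority-class oversampling; real patients are always False.
    ``feature_roles`` carries generator ground truth (per-feature role tags)
    when the cohort was simulated, else None.
    """

    features: pd.DataFrame
    labels: pd.Series
    metadata: pd.DataFrame
    histotype: pd.Series | None = None
    is_synthetic: pd.Series | None = None
    feature_roles: dict[str, str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        idx = self.features.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise CohortError(f"duplicate patient ids: {dupes}")
        if self.features.columns.has_duplicates:
            raise CohortError("duplicate feature names")
        if self.is_synthetic is None:
            self.is_synthetic = pd.Series(False, index=idx)
        for name, obj in [
            ("labels", self.labels),
            ("metadata", self.metadata),
            ("is_synthetic", self.is_synthetic),
        ] + ([("histotype", self.histotype)] if self.histotype is not None else []):
            if not obj.index.equals(idx):
                raise CohortError(f"{name} index does not match the feature matrix")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise SchemaError(f"missing metadata columns: {missing}")
        vals = self.features.to_numpy(dtype=float, na_value=np.nan)
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ParseError(
                f"non-finite/missing feature value at patient {idx[r]!r}, "
                f"feature {self.features.columns[c]!r}"
            )
        bad = set(self.labels.unique()) - {LABEL_BENIGN, LABEL_MALIGNANT}
        if bad:
            raise CohortError(f"labels must be 0 (benign) or 1 (malignant); found {sorted(bad)}")
        cont = self.metadata[list(CONTINUOUS_PARAMETERS)].to_numpy(dtype=float)
        if not (np.isfinite(cont).all() and (cont > 0).all()):
            raise CohortError("continuous acquisition parameters must be finite and > 0")
        if self.metadata[list(CATEGORICAL_PARAMETERS)].isna().any().any():
            raise CohortError("categorical acquisition parameters must be present for every patient")

    # -- basic views ----------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def patient_ids(self) -> list:
        return list(self.features.index)

    def label_counts(self) -> dict[int, int]:
        vc = self.labels.value_counts()
        return {int(k): int(v) for k, v in vc.items()}

    # -- derived cohorts ------------------------------------------------

    def take(self, ids) -> "Cohort":
        """Row subset by patient ids (order preserved as given)."""
        ids = list(ids)
        return Cohort(
            features=self.features.loc[ids],
            labels=self.labels.loc[ids],
            metadata=self.metadata.loc[ids],
            histotype=None if self.histotype is None else self.histotype.loc[ids],
            is_synthetic=self.is_synthetic.loc[ids],
            feature_roles=self.feature_roles,
        )

    def select_features(self, names) -> "Cohort":
        names = list(names)
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise SchemaError(f"unknown features requested: {missing}")
        return replace(self, features=self.features[names])

    def with_features(self, features: pd.DataFrame) -> "Cohort":
        """Same patients, replaced feature matrix (e.g. after standardization)."""
        return replace(self, features=features)

    def real_rows(self) -> "Cohort":
        """Drop synthetic (oversampled) rows."""
        keep = self.is_synthetic[~self.is_synthetic].index
        return self.take(keep)


# ---------------------------------------------------------------------------
# I/O: one CSV row per patient, header row, metadata columns named exactly as
# in METADATA_COLUMNS; a JSON sidecar echoes shape and label counts.
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {"patient_id": "patient_id", "label": "label", "histotype": "histotype"}


def load_feature_table(path, schema: dict | None = None) -> Cohort:
    """Read a delimited feature table into a validated :class:`Cohort`.

    ``schema`` maps the roles ``patient_id``/``label``/``histotype`` to column
    names; unmapped roles fall back to those literal names.  Every column not
    claimed by a role or by acquisition metadata is treated as a feature and
    coerced to float.
    """
    path = Path(path)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    raw = pd.read_csv(path)
    for role in ("patient_id", "label"):
        if schema[role] not in raw.columns:
            raise SchemaError(f"column {schema[role]!r} (role {role}) not found in {path.name}")
    missing_meta = [c for c in METADATA_COLUMNS if c not in raw.columns]
    if missing_meta:
        raise SchemaError(f"missing metadata columns in {path.name}: {missing_meta}")

    ids = raw[schema["patient_id"]].astype(str)
    if ids.duplicated().any():
        raise CohortError(f"duplicate patient id in {path.name}: "
                          f"{ids[ids.duplicated()].iloc[0]!r}")
    raw = raw.set_index(ids.rename("patient_id"))

    non_feature = set(schema.values()) | set(METADATA_COLUMNS) | {"is_synthetic"}
    feat_cols = [c for c in raw.columns if c not in non_feature]
    coerced = {}
    for c in feat_cols:
        col = pd.to_numeric(raw[c], errors="coerce")
        bad = col.isna() & raw[c].notna()
        if bad.any():
            raise ParseError(
                f"non-numeric value {raw.loc[bad.idxmax(), c]!r} in feature column "
                f"{c!r}, row {bad.idxmax()!r}"
            )
        if col.isna().any():
            raise ParseError(f"missing value in feature column {c!r}, row {col.isna().idxmax()!r}")
        coerced[c] = col.astype(float)
    feats = pd.DataFrame(coerced, index=raw.index)

    histo = None
    if schema.get("histotype") in raw.columns:
        histo = raw[schema["histotype"]].astype(str).rename("histotype")
    synth = None
    if "is_synthetic" in raw.columns:
        synth = raw["is_synthetic"].astype(bool)
    return Cohort(
        features=feats,
        labels=raw[schema["label"]].astype(int).rename("label"),
        metadata=raw[list(METADATA_COLUMNS)].copy(),
        histotype=histo,
        is_synthetic=synth,
    )


def write_feature_table(cohort: Cohort, path, ground_truth_sidecar: bool = True) -> Path:
    """Write a cohort as CSV plus a JSON sidecar (``<stem>.meta.json``)."""
    path = Path(path)
    out = pd.DataFrame(index=cohort.features.index)
    out["label"] = cohort.labels
    if cohort.histotype is not None:
        out["histotype"] = cohort.histotype
    for c in METADATA_COLUMNS:
        out[c] = cohort.metadata[c]
    if bool(cohort.is_synthetic.any()):
        out["is_synthetic"] = cohort.is_synthetic
    out = pd.concat([out, cohort.features], axis=1)
    out.index.name = "patient_id"
    out.to_csv(path)

    sidecar = {
        "n_patients": cohort.n_patients,
        "n_features": cohort.n_features,
        "feature_names": cohort.feature_names,
        "label_counts": {str(k): v for k, v in sorted(cohort.label_counts().items())},
    }
    if ground_truth_sidecar and cohort.feature_roles is not None:
        sidecar["feature_roles"] = cohort.feature_roles
    meta_path = path.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------


def _per_class_test_counts(class_sizes: dict, fraction: float) -> dict:
    """Largest-remainder apportionment of round(n*fraction) test slots.

    Each class gets floor(n_c*fraction); remaining slots (up to the rounded
    total) go to classes by descending fractional remainder, larger class
    first on ties, then label order.
    """
    total_target = int(round(sum(class_sizes.values()) * fraction))
    exact = {c: n * fraction for c, n in class_sizes.items()}
    counts = {c: int(np.floor(e)) for c, e in exact.items()}
    leftover = total_target - sum(counts.values())
    order = sorted(
        class_sizes,
        key=lambda c: (-(exact[c] - counts[c]), -class_sizes[c], c),
    )
    for c in order[:max(leftover, 0)]:
        counts[c] += 1
    # over-allocation (all remainders zero but rounding up): trim largest class
    while sum(counts.values()) > total_target:
        counts[max(counts, key=lambda c: (class_sizes[c], c))] -= 1
    return counts


def stratified_split(cohort: Cohort, spec: SplitSpec) -> tuple[Cohort, Cohort]:
    """Random train/test split, stratified on the outcome label.

    Per-class test counts follow :func:`_per_class_test_counts`; with the
    85-patient study composition (51 malignant / 34 benign) and a 0.2 test
    fraction this yields the 17-patient test set (10 / 7).  Deterministic
    under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ids = np.asarray(cohort.patient_ids, dtype=object)
    if spec.stratify_on_label:
        labels = cohort.labels.to_numpy()
        classes = sorted(set(labels.tolist()))
        if any((labels == c).sum() < 2 for c in classes):
            raise CohortError("each class needs at least 2 members to split")
        counts = _per_class_test_counts(
            {c: int((labels == c).sum()) for c in classes}, spec.test_fraction
        )
        zero = [c for c, k in counts.items() if k == 0]
        if zero:
            raise CohortError(
                f"classes {zero} would receive 0 test members; use a larger test_fraction"
            )
        test_ids: list = []
        for c in classes:
            pool = ids[labels == c]
            pick = rng.permutation(len(pool))[: counts[c]]
            test_ids.extend(pool[np.sort(pick)].tolist())
    else:
        k = int(round(len(ids) * spec.test_fraction))
        if k == 0 or k == len(ids):
            raise CohortError("split would leave an empty partition")
        pick = rng.permutation(len(ids))[:k]
        test_ids = ids[np.sort(pick)].tolist()
    test_set = set(test_ids)
    train_ids = [i for i in cohort.patient_ids if i not in test_set]
    return cohort.take(train_ids), cohort.take(test_ids)
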