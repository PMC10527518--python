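"""Synthetic CT-radiomics cohort generator.

Real radiomic feature tables for small renal masses are not publicly
deposited, so the pipeline is exercised on simulated cohorts that reproduce
the statistical structure the method has to cope with:

* a benign/malignant outcome with the study's class imbalance
  (default 51 malignant vs 34 benign, 40% benign fraction),
* blocks of near-duplicate features (pairwise |r| > 0.99) mimicking the
  heavily redundant texture-feature families (GLCM/GLRLM/GLSZM/...),
* features confounded with the scanner model (additive per-scanner shifts),
  with reconstruction kernels nested inside scanners as on real devices,
* a handful of genuinely class-informative features with a chosen
  standardized mean difference, and
* acquisition metadata drawn from the study's ranges (3 scanner models,
  5 kernels, pixel spacing 0.61-0.98 mm, slice thickness 1.5-2.5 mm,
  tube voltage 100-130 kVp).

Every feature's ground-truth role is recorded so that recovery, calibration
and false-positive rates of the downstream pipeline can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Cohort, METADATA_COLUMNS

# Study-cohort histotype composition (counts sum to 85)
TABLE1_HISTOTYPES: dict[str, int] = {
    "clear_cell_rcc": 37,
    "chromophobe_rcc": 7,
    "papillary_rcc": 7,
    "oncocytoma": 25,
    "lipid_poor_aml": 7,
    "leiomyoma": 2,
}
MALIGNANT_HISTOTYPES = frozenset({"clear_cell_rcc", "chromophobe_rcc", "papillary_rcc"})

DEFAULT_SCANNERS = (
    "SOMATOM_Emotion_6",
    "SOMATOM_Sensation_Cardiac_64",
    "SOMATOM_Definition_Flash",
)
#: reconstruction kernels nested within scanner, as on the physical devices
DEFAULT_KERNELS_BY_SCANNER: dict[str, tuple[str, ...]] = {
    "SOMATOM_Emotion_6": ("B31s", "B40s"),
    "SOMATOM_Sensation_Cardiac_64": ("B20f", "B30f"),
    "SOMATOM_Definition_Flash": ("Br32f",),
}

ROLE_NOISE = "noise"
ROLE_INFORMATIVE = "informative"
ROLE_BATCH = "batch_affected"
ROLE_ANCHOR = "redundant_anchor"
ROLE_MEMBER = "redundant_member"


class GeneratorConfigError(ValueError):
    """Role counts or ranges in a GeneratorConfig are inconsistent."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: the Table-1 histotype counts,
    107 features of which ~25% sit in near-duplicate blocks and ~30% of the
    non-redundant remainder carry scanner batch effects, and acquisition
    metadata drawn uniformly from the reported ranges.

    Parameters
    ----------
    n_per_histotype
        Patients per histotype; malignancy follows MALIGNANT_HISTOTYPES.
    n_features
        Total feature count (the study extracted ~107 usable features).
    n_informative, effect_size
        Number of class-informative features and their standardized mean
        difference (malignant minus benign, in noise-sd units).
    n_redundant_blocks, block_size, redundancy_noise_sd
        Near-duplicate blocks: each block is one anchor plus
        ``block_size - 1`` members equal to the anchor plus N(0, sd^2) jitter;
        at the default sd = 0.05 the pairwise correlation is ~0.999.
    n_batch_affected, batch_shift
        Features shifted additively by ``batch_shift * scanner_index``
        standard deviations — a scanner batch effect the reproducibility
        chain is expected to remove.
    """

    n_per_histotype: dict[str, int] = field(
        default_factory=lambda: dict(TABLE1_HISTOTYPES)
    )
    n_features: int = 107
    n_informative: int = 5
    effect_size: float = 1.5
    n_redundant_blocks: int = 9
    block_size: int = 4
    redundancy_noise_sd: float = 0.05
    n_batch_affected: int = 24
    batch_shift: float = 1.0
    scanner_models: tuple[str, ...] = DEFAULT_SCANNERS
    kernels_by_scanner: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_KERNELS_BY_SCANNER)
    )
    pixel_spacing_range: tuple[float, float] = (0.61, 0.98)
    thickness_range: tuple[float, float] = (1.5, 2.5)
    kvp_range: tuple[float, float] = (100.0, 130.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_per_histotype.values()):
            raise GeneratorConfigError("histotype counts must be non-negative")
        if min(self.n_informative, self.n_batch_affected, self.n_redundant_blocks) < 0:
            raise GeneratorConfigError("role counts must be non-negative")
        if self.n_redundant_blocks > 0 and self.block_size < 2:
            raise GeneratorConfigError("block_size must be >= 2 (anchor plus members)")
        if self.n_role_features > self.n_features:
            raise GeneratorConfigError(
                f"role features ({self.n_role_features}) exceed n_features ({self.n_features})"
            )
        if self.redundancy_noise_sd <= 0:
            raise GeneratorConfigError("redundancy_noise_sd must be positive")
        for lo, hi in (self.pixel_spacing_range, self.thickness_range, self.kvp_range):
            if not 0 < lo < hi:
                raise GeneratorConfigError("metadata ranges must be ordered and positive")
        missing = [s for s in self.scanner_models if s not in self.kernels_by_scanner]
        if missing:
            raise GeneratorConfigError(f"no kernel set for scanners {missing}")

    @property
    def n_role_features(self) -> int:
        return (
            self.n_informative
            + self.n_batch_affected
            + self.n_redundant_blocks * self.block_size
        )

    def to_dict(self) -> dict:
        return {
            "n_per_histotype": dict(self.n_per_histotype),
            "n_features": self.n_features,
            "n_informative": self.n_informative,
            "effect_size": self.effect_size,
            "n_redundant_blocks": self.n_redundant_blocks,
            "block_size": self.block_size,
            "redundancy_noise_sd": self.redundancy_noise_sd,
            "n_batch_affected": self.n_batch_affected,
            "batch_shift": self.batch_shift,
            "scanner_models": list(self.scanner_models),
            "kernels_by_scanner": {k: list(v) for k, v in self.kernels_by_scanner.items()},
            "pixel_spacing_range": list(self.pixel_spacing_range),
            "thickness_range": list(self.thickness_range),
            "kvp_range": list(self.kvp_range),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("scanner_models",):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("pixel_spacing_range", "thickness_range", "kvp_range"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        if "kernels_by_scanner" in d:
            d["kernels_by_scanner"] = {k: tuple(v) for k, v in d["kernels_by_scanner"].items()}
        return cls(**d)


def paper_preset(**overrides) -> GeneratorConfig:
    """The default study-composition configuration, with optional overrides."""
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Draw a synthetic cohort; deterministic under ``config.seed``.

    Features are standard normal noise except for their planted role:
    informative features add ``effect_size`` to malignant patients, batch
    features add ``batch_shift * scanner_index``, redundant-block members
    equal their anchor plus small jitter.  Roles are scattered over feature
    positions (seeded permutation) so that feature order carries no signal.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    histotypes: list[str] = []
    for h in sorted(config.n_per_histotype):
        histotypes.extend([h] * config.n_per_histotype[h])
    n = len(histotypes)
    if n == 0:
        raise GeneratorConfigError("empty cohort: all histotype counts are zero")
    labels = np.array([1 if h in MALIGNANT_HISTOTYPES else 0 for h in histotypes])
    ids = [f"P{i:03d}" for i in range(1, n + 1)]

    # metadata
    s_idx = rng.integers(0, len(config.scanner_models), size=n)
    scanners = [config.scanner_models[i] for i in s_idx]
    kernels = [
        config.kernels_by_scanner[s][rng.integers(0, len(config.kernels_by_scanner[s]))]
        for s in scanners
    ]
    meta = pd.DataFrame(
        {
            "scanner_model": scanners,
            "convolution_kernel": kernels,
            "pixel_spacing_mm": rng.uniform(*config.pixel_spacing_range, size=n),
            "slice_thickness_mm": rng.uniform(*config.thickness_range, size=n),
            "tube_voltage_kvp": rng.uniform(*config.kvp_range, size=n),
        },
        index=pd.Index(ids, name="patient_id"),
    )

    p = config.n_features
    width = max(3, len(str(p - 1)))
    names = [f"rf_{j:0{width}d}" for j in range(p)]
    X = rng.standard_normal((n, p))

    positions = rng.permutation(p)
    cursor = 0
    roles = {nm: ROLE_NOISE for nm in names}

    info_pos = positions[cursor : cursor + config.n_informative]
    cursor += config.n_informative
    for j in info_pos:
        X[:, j] += config.effect_size * labels
        roles[names[j]] = ROLE_INFORMATIVE

    batch_pos = positions[cursor : cursor + config.n_batch_affected]
    cursor += config.n_batch_affected
    for j in batch_pos:
        X[:, j] += config.batch_shift * s_idx
        roles[names[j]] = ROLE_BATCH

    for _ in range(config.n_redundant_blocks):
        block = positions[cursor : cursor + config.block_size]
        cursor += config.block_size
        anchor = block[0]
        roles[names[anchor]] = ROLE_ANCHOR
        for j in block[1:]:
            X[:, j] = X[:, anchor] + rng.normal(0.0, config.redundancy_noise_sd, size=n)
            roles[names[j]] = ROLE_MEMBER

    feats = pd.DataFrame(X, index=meta.index, columns=names)
    return Cohort(
        features=feats,
        labels=pd.Series(labels, index=meta.index, name="label"),
        metadata=meta,
        histotype=pd.Series(histotypes, index=meta.index, name="histotype"),
        feature_roles=roles,
    )


def permute_labels(cohort: Cohort, seed: int = 0) -> Cohort:
    """Random permutation of the outcome labels over patients.

    Destroys any feature-outcome association while keeping the label
    marginal and all features/metadata intact — the standard null for
    checking that the pipeline does not manufacture signal.
    """
    rng = np.random.default_rng(seed)
    shuffled = cohort.labels.to_numpy()[rng.permutation(cohort.n_patients)]
    return Cohort(
        features=cohort.features,
        labels=pd.Series(shuffled, index=cohort.labels.index, name="label"),
        metadata=cohort.metadata,
        histotype=None,  # histotype no longer consistent with the labels
        is_synthetic=cohort.is_synthetic,
        feature_roles=cohort.feature_roles,
    )


def ground_truth(cohort: Cohort) -> dict[str, str]:
    """Per-feature role tags of a generated cohort.

    Raises if the cohort did not come from :func:`generate_cohort`.
    """
    if cohort.feature_roles is None:
        raise ValueError("cohort carries no generator ground truth")
    return {nm: cohort.feature_roles[nm] for nm in cohort.feature_names}
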