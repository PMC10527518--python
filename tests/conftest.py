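import numpy as np
import pandas as pd
import pytest

from srmrad import Cohort, GeneratorConfig, SplitSpec, generate_cohort, stratified_split


@pytest.fixture(scope="session")
def preset_cohort() -> Cohort:
    """Default study-composition synthetic cohort (85 patients, 107 features)."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def preset_split(preset_cohort):
    return stratified_split(preset_cohort, SplitSpec(0.2, True, 11))


def tiny_cohort(n_features: int = 2) -> Cohort:
    """Hand-built 4-patient cohort for I/O and contract tests."""
    ids = pd.Index([f"P{i}" for i in range(1, 5)], name="patient_id")
    rng = np.random.default_rng(5)
    feats = pd.DataFrame(
        rng.normal(size=(4, n_features)),
        index=ids,
        columns=[f"rf_{j:03d}" for j in range(n_features)],
    )
    meta = pd.DataFrame(
        {
            "scanner_model": ["A", "A", "B", "B"],
            "convolution_kernel": ["B31s", "B40s", "B20f", "B20f"],
            "pixel_spacing_mm": [0.7, 0.8, 0.9, 0.65],
            "slice_thickness_mm": [1.5, 2.0, 2.5, 1.5],
            "tube_voltage_kvp": [100.0, 110.0, 120.0, 130.0],
        },
        index=ids,
    )
    return Cohort(
        features=feats,
        labels=pd.Series([0, 1, 0, 1], index=ids, name="label"),
        metadata=meta,
        histotype=pd.Series(["oncocytoma", "clear_cell_rcc"] * 2, index=ids, name="histotype"),
    )
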