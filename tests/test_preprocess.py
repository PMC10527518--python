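"""Redundancy elimination, z-score transfer, RWO oversampling, balancing."""

import numpy as np
import pandas as pd
import pytest

from srmrad import (
    GeneratorConfig,
    balance_training_subset,
    apply_standardizer,
    eliminate_redundant,
    fit_standardizer,
    generate_cohort,
    rwo_oversample,
)
from srmrad.preprocess import PreprocessError

from conftest import tiny_cohort


def _frame(seed=0, n=85, cols=("a", "b")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, len(cols))), columns=list(cols))


class TestRedundancy:
    def test_affine_dependent_pair_drops_later_name(self):
        df = _frame(cols=("a",))
        df["b"] = 2 * df["a"] + 5
        reduced, report = eliminate_redundant(df, 0.99)
        assert list(reduced.columns) == ["a"]
        (dropped, partner, r), = report.dropped
        assert (dropped, partner) == ("b", "a")
        assert r == pytest.approx(1.0)

    def test_independent_features_both_retained(self):
        reduced, report = eliminate_redundant(_frame(seed=1), 0.99)
        assert list(reduced.columns) == ["a", "b"] and not report.dropped

    def test_generator_block_leaves_one_survivor(self):
        cfg = GeneratorConfig(
            n_informative=0, n_batch_affected=0, n_redundant_blocks=1,
            block_size=3, redundancy_noise_sd=0.01, n_features=5, seed=9,
        )
        c = generate_cohort(cfg)
        block = sorted(f for f, r in c.feature_roles.items() if r.startswith("redundant"))
        reduced, report = eliminate_redundant(c.features, 0.99)
        survivors = [f for f in reduced.columns if f in block]
        assert len(survivors) == 1
        # brute-force rule applied by hand: earliest name in the block survives
        assert survivors[0] == block[0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_no_surviving_pair_exceeds_threshold(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(60, 6))
        df = pd.DataFrame(base, columns=[f"f{j}" for j in range(6)])
        for j in range(3):  # plant near-duplicates
            df[f"g{j}"] = df[f"f{j}"] + rng.normal(0, 0.01, 60)
        reduced, _ = eliminate_redundant(df, 0.99)
        if reduced.shape[1] > 1:
            corr = reduced.corr().abs().to_numpy()
            assert corr[~np.eye(len(corr), dtype=bool)].max() <= 0.99

    def test_zero_variance_column_reported_distinctly(self):
        df = _frame(seed=2)
        df["const"] = 3.14
        reduced, report = eliminate_redundant(df, 0.99)
        assert "const" not in reduced.columns
        entry = next(e for e in report.dropped if e[0] == "const")
        assert entry[1] is None and entry[2] is None


class TestStandardizer:
    def test_hand_arithmetic(self):
        params = fit_standardizer(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert params.mean["x"] == pytest.approx(2.0)
        assert params.sd["x"] == pytest.approx(1.0)  # sample sd, n-1

    def test_fit_on_standardized_data_is_identity_params(self):
        df = _frame(seed=3)
        z = apply_standardizer(fit_standardizer(df), df)
        p2 = fit_standardizer(z)
        assert np.allclose(p2.mean, 0.0, atol=1e-12)
        assert np.allclose(p2.sd, 1.0, atol=1e-12)

    def test_applied_to_fitting_matrix_gives_unit_columns(self):
        df = _frame(seed=4)
        z = apply_standardizer(fit_standardizer(df), df)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_transfer_uses_stored_params_not_refit(self):
        """A +10 shift in unseen data must show up as 10/sd, not be absorbed."""
        df = _frame(seed=5)
        params = fit_standardizer(df)
        z_shift = apply_standardizer(params, df + 10.0)
        expected = 10.0 / params.sd
        assert np.allclose(z_shift.mean() - 0.0, expected, atol=1e-10)

    def test_empty_matrix_passes_through(self):
        params = fit_standardizer(_frame(seed=6))
        out = apply_standardizer(params, _frame(seed=6).iloc[:0])
        assert out.empty and list(out.columns) == ["a", "b"]

    def test_unknown_feature_rejected(self):
        params = fit_standardizer(_frame(seed=7))
        with pytest.raises(PreprocessError, match="not covered"):
            apply_standardizer(params, _frame(seed=7, cols=("a", "zzz")))

    def test_zero_variance_directs_to_redundancy_stage(self):
        df = _frame(seed=8)
        df["c"] = 1.0
        with pytest.raises(PreprocessError, match="eliminate_redundant"):
            fit_standardizer(df)


class TestRWO:
    def test_zero_requested_rows(self):
        out, src = rwo_oversample(_frame(seed=9, n=10), 0, seed=0)
        assert out.empty and len(src) == 0

    def test_constant_feature_has_zero_step(self):
        df = _frame(seed=10, n=10)
        df["const"] = 7.0
        out, src = rwo_oversample(df, 50, seed=1)
        assert (out["const"] == 7.0).all()

    def test_deterministic_under_seed(self):
        df = _frame(seed=11, n=20)
        a, _ = rwo_oversample(df, 30, seed=5)
        b, _ = rwo_oversample(df, 30, seed=5)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_single_row_minority_rejected(self):
        with pytest.raises(PreprocessError):
            rwo_oversample(_frame(seed=12, n=1), 5, seed=0)


class TestBalance:
    def test_41_27_becomes_41_41_with_flagged_synthetics(self, preset_cohort):
        from srmrad import SplitSpec, stratified_split

        train, _ = stratified_split(preset_cohort, SplitSpec(0.2, True, 3))
        assert train.label_counts() == {1: 41, 0: 27}
        balanced = balance_training_subset(train, seed=0)
        assert balanced.label_counts() == {1: 41, 0: 41}
        assert int(balanced.is_synthetic.sum()) == 14
        # synthetic flags sit only on appended benign rows
        assert (balanced.labels[balanced.is_synthetic] == 0).all()
        assert not balanced.is_synthetic[train.patient_ids].any()

    def test_already_balanced_is_identity(self):
        c = tiny_cohort()
        assert balance_training_subset(c, seed=0) is c

    def test_single_class_rejected(self):
        c = tiny_cohort()
        only_benign = c.take([p for p in c.patient_ids if c.labels[p] == 0])
        with pytest.raises(PreprocessError):
            balance_training_subset(only_benign, seed=0)

    def test_synthetic_rows_preserve_minority_mean(self, preset_cohort):
        from srmrad import SplitSpec, stratified_split

        train, _ = stratified_split(preset_cohort, SplitSpec(0.2, True, 3))
        minority = train.features[train.labels == 0]
        synth, _ = rwo_oversample(minority, 4000, seed=2)
        se = minority.std(ddof=0) / np.sqrt(len(minority))
        assert (np.abs(synth.mean() - minority.mean()) < 4 * se).all()
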