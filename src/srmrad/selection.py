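"""First MCCV step: stability feature selection with a Mann-Whitney filter.

Each of the (default 100) Monte-Carlo rounds redraws an 80/20 stratified
subset of the training set, reruns the whole preprocessing stack on the 80%
part only (redundancy elimination, z-scoring, RWO class balancing, and the
acquisition-reproducibility chain on the real rows), and then applies a
two-sided Mann-Whitney test per surviving feature.  A feature scores one
point in a round when its p-value is below ``mw_alpha``; the signature is
the top-K cumulative scorers, so only features selected *stably* across
perturbed training subsets make it in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, SplitSpec, stratified_split
from .preprocess import (
    apply_standardizer,
    balance_training_subset,
    eliminate_redundant,
    fit_standardizer,
)
from .reproducibility import ReproducibilityReport, apply_reproducibility_chain


class SelectionError(ValueError):
    pass


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U of ``x`` (pairs won plus half of ties) and two-sided p.

    Exact enumeration when the combined sample is small (n <= 20, no ties),
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise SelectionError("Mann-Whitney needs two non-empty samples")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _mw_all_features(X: np.ndarray, group1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Mann-Whitney over feature columns.

    Tie-corrected normal approximation with continuity correction — the
    MCCV filter always operates at combined n > 20, where this matches the
    scalar :func:`mann_whitney` path (asserted in the test suite).
    """
    n = X.shape[0]
    n1 = int(group1.sum())
    n2 = n - n1
    ranks = stats.rankdata(X, axis=0)
    u1 = ranks[group1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0
    tie_sums = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        counts = np.unique(X[:, j], return_counts=True)[1]
        tie_sums[j] = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_sums / (n * (n - 1)))
    sd = np.sqrt(var)
    num = np.abs(u1 - mean) - 0.5  # continuity correction
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, np.maximum(num, 0.0) / sd, 0.0)
    p = np.where(sd > 0, 2.0 * stats.norm.sf(z), 1.0)
    return u1, np.minimum(p, 1.0)


@dataclass(frozen=True)
class FsSettings:
    """Per-round preprocessing knobs of the selection MCCV."""

    subset_fraction: float = 0.2  # held-out share of each round's inner split
    redundancy_threshold: float = 0.99
    alpha: float = 0.05  # reproducibility chain, categorical tests
    rho_threshold: float = 0.75  # reproducibility chain, continuous tests
    mw_alpha: float = 0.05
    mw_on_balanced: bool = True  # False: test the unbalanced 80% subset instead
    chain_per_round: bool = True  # False: one global chain on the full training set


@dataclass
class RoundResult:
    seed: int
    selected: list[str]
    pvalues: dict[str, float]  # every feature that reached the MW filter
    # per-round accounting (how many features each stage consumed/removed)
    n_features_in: int = 0
    n_after_redundancy: int = 0
    chain_removed: dict[str, int] = field(default_factory=dict)


@dataclass
class FeatureScoreBoard:
    """Cumulative selection counts over MCCV rounds.

    A feature's score is the number of rounds in which it both survived
    that round's preprocessing and passed the Mann-Whitney filter; features
    eliminated in a round simply score 0 for it.  ``mean_p`` (mean MW
    p-value over the rounds in which the feature was actually tested) is
    the tie-break key for the top-K cut.
    """

    feature_names: list[str]
    rounds: int = 0
    scores: pd.Series = None  # type: ignore[assignment]
    per_round_selected: list[list[str]] = field(default_factory=list)
    round_seeds: list[int] = field(default_factory=list)
    _p_sum: pd.Series = None  # type: ignore[assignment]
    _p_count: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        idx = pd.Index(self.feature_names, name="feature")
        if self.scores is None:
            self.scores = pd.Series(0, index=idx, dtype=int)
        if self._p_sum is None:
            self._p_sum = pd.Series(0.0, index=idx)
        if self._p_count is None:
            self._p_count = pd.Series(0, index=idx, dtype=int)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def mean_p(self) -> pd.Series:
        """Mean MW p over tested rounds; 1.0 for never-tested features."""
        with np.errstate(invalid="ignore"):
            out = self._p_sum / self._p_count
        return out.fillna(1.0)

    def add_round(self, result: RoundResult) -> None:
        self.rounds += 1
        self.round_seeds.append(result.seed)
        self.per_round_selected.append(list(result.selected))
        if result.selected:
            self.scores.loc[result.selected] += 1
        for name, p in result.pvalues.items():
            self._p_sum.loc[name] += p
            self._p_count.loc[name] += 1

    def merge(self, other: "FeatureScoreBoard") -> "FeatureScoreBoard":
        """Elementwise combination of two boards over disjoint seed blocks."""
        if self.feature_names != other.feature_names:
            raise SelectionError("boards cover different feature sets")
        merged = FeatureScoreBoard(feature_names=list(self.feature_names))
        merged.rounds = self.rounds + other.rounds
        merged.scores = self.scores + other.scores
        merged.per_round_selected = self.per_round_selected + other.per_round_selected
        merged.round_seeds = self.round_seeds + other.round_seeds
        merged._p_sum = self._p_sum + other._p_sum
        merged._p_count = self._p_count + other._p_count
        return merged

    def to_json(self) -> str:
        return json.dumps(
            {
                "rounds": self.rounds,
                "round_seeds": self.round_seeds,
                "scores": {n: int(s) for n, s in self.scores.items()},
                "mean_p": {n: float(p) for n, p in self.mean_p.items()},
                "per_round_selected": self.per_round_selected,
            },
            indent=2,
            sort_keys=True,
        )


def fs_round(
    training_set: Cohort,
    round_seed: int,
    settings: FsSettings | None = None,
    global_chain_kept: list[str] | None = None,
) -> RoundResult:
    """One selection round: inner 80/20 split, preprocessing, MW filter."""
    st = settings or FsSettings()
    work, _held_out = stratified_split(
        training_set, SplitSpec(st.subset_fraction, True, round_seed)
    )

    feats, _red = eliminate_redundant(work.features, st.redundancy_threshold)
    params = fit_standardizer(feats)
    z = apply_standardizer(params, feats)
    work_z = work.with_features(z)

    chain_removed: dict[str, int] = {}
    if st.chain_per_round or global_chain_kept is None:
        kept, rep = apply_reproducibility_chain(
            work_z, alpha=st.alpha, rho_threshold=st.rho_threshold
        )
        chain_removed = rep.removal_counts()
    else:
        kept = [n for n in z.columns if n in set(global_chain_kept)]

    mw_input = balance_training_subset(work_z, seed=round_seed) if st.mw_on_balanced else work_z
    malignant = (mw_input.labels == 1).to_numpy()
    X = mw_input.features[kept].to_numpy(dtype=float)
    _u, p = _mw_all_features(X, malignant)
    pvalues = {name: float(pv) for name, pv in zip(kept, p)}
    selected = [name for name, pv in pvalues.items() if pv < st.mw_alpha]
    return RoundResult(
        seed=round_seed,
        selected=selected,
        pvalues=pvalues,
        n_features_in=training_set.n_features,
        n_after_redundancy=feats.shape[1],
        chain_removed=chain_removed,
    )


def run_fs_mccv(
    training_set: Cohort,
    rounds: int = 100,
    base_seed: int = 0,
    settings: FsSettings | None = None,
) -> FeatureScoreBoard:
    """Run the selection MCCV with per-round seeds base_seed+1..base_seed+rounds."""
    if rounds < 1:
        raise SelectionError("rounds must be >= 1")
    st = settings or FsSettings()
    global_kept: list[str] | None = None
    if not st.chain_per_round:
        global_kept, _ = apply_reproducibility_chain(
            training_set, alpha=st.alpha, rho_threshold=st.rho_threshold
        )
    board = FeatureScoreBoard(feature_names=training_set.feature_names)
    for r in range(1, rounds + 1):
        board.add_round(fs_round(training_set, base_seed + r, st, global_kept))
    return board


def select_signature(board: FeatureScoreBoard, k: int = 10) -> list[str]:
    """Top-``k`` features by cumulative score.

    Ties are broken by ascending mean Mann-Whitney p, then lexicographic
    name, so the signature is fully deterministic.
    """
    if board.n_features < k:
        raise SelectionError(
            f"scoreboard has only {board.n_features} features, cannot select {k}"
        )
    mean_p = board.mean_p
    ranked = sorted(
        board.feature_names,
        key=lambda n: (-int(board.scores[n]), float(mean_p[n]), n),
    )
    return ranked[:k]
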