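"""End-to-end orchestration: split -> selection MCCV -> signature -> tuning
-> final training MCCV with test evaluation, with every artifact written to
a run directory and a manifest that suffices to replay the run exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import Cohort, SplitSpec, load_feature_table, stratified_split, write_feature_table
from .model import ModelConfig, PerformanceSummary, TuningResult, default_grid, run_training_mccv, tune
from .selection import FeatureScoreBoard, FsSettings, run_fs_mccv, select_signature
from .simulate import GeneratorConfig, generate_cohort

log = logging.getLogger("srmrad")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Every constant of the analysis, with the study's values as defaults.

    ``cohort_path`` loads a feature table from disk; when None a synthetic
    cohort is generated from ``generator``.  Sub-seeds for the split, the
    selection MCCV and the training MCCV are derived from ``seed`` so one
    integer pins the whole run.
    """

    cohort_path: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    test_fraction: float = 0.2
    redundancy_threshold: float = 0.99
    alpha: float = 0.05
    rho_threshold: float = 0.75
    fs_rounds: int = 100
    train_rounds: int = 100
    signature_size: int = 10
    reductions: tuple[str, ...] = ("pca", "ica")
    dims: tuple[int, ...] = (2, 3)
    neighbors: tuple[int, ...] = (3, 5, 7, 9, 11, 13, 15)
    chain_per_round: bool = True
    mw_on_balanced: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ConfigError("test_fraction must be in (0, 1)")
        for name in ("redundancy_threshold", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if not 0 < self.rho_threshold <= 1:
            raise ConfigError("rho_threshold must be in (0, 1]")
        if min(self.fs_rounds, self.train_rounds, self.signature_size) < 1:
            raise ConfigError("rounds and signature_size must be >= 1")

    # deterministic sub-seeds, all < 2**31
    @property
    def split_seed(self) -> int:
        return (self.seed * 4 + 1) % (2**31)

    @property
    def fs_seed(self) -> int:
        return (self.seed * 4 + 2) % (2**31)

    @property
    def train_seed(self) -> int:
        return (self.seed * 4 + 3) % (2**31)

    def fs_settings(self) -> FsSettings:
        return FsSettings(
            redundancy_threshold=self.redundancy_threshold,
            alpha=self.alpha,
            rho_threshold=self.rho_threshold,
            mw_alpha=self.alpha,
            mw_on_balanced=self.mw_on_balanced,
            chain_per_round=self.chain_per_round,
        )

    def grid(self) -> list[ModelConfig]:
        return default_grid(self.reductions, self.dims, self.neighbors)

    def to_dict(self) -> dict:
        return {
            "cohort_path": self.cohort_path,
            "generator": self.generator.to_dict(),
            "test_fraction": self.test_fraction,
            "redundancy_threshold": self.redundancy_threshold,
            "alpha": self.alpha,
            "rho_threshold": self.rho_threshold,
            "fs_rounds": self.fs_rounds,
            "train_rounds": self.train_rounds,
            "signature_size": self.signature_size,
            "reductions": list(self.reductions),
            "dims": list(self.dims),
            "neighbors": list(self.neighbors),
            "chain_per_round": self.chain_per_round,
            "mw_on_balanced": self.mw_on_balanced,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        for key in ("reductions", "dims", "neighbors"):
            if key in d:
                d[key] = tuple(d[key])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: expected a mapping at the top level")
        return cls.from_dict(payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class PipelineResult:
    run_dir: Path
    cohort: Cohort
    train: Cohort
    test: Cohort
    board: FeatureScoreBoard
    signature: list[str]
    tuning: TuningResult
    performance: PerformanceSummary


def _dump(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Execute the full two-step MCCV pipeline and write all artifacts.

    The run directory receives: the (generated or echoed) cohort table, the
    split membership, the feature scoreboard, the signature, the tuning
    curve, the final per-round and summary performance, and
    ``manifest.json`` — a complete replayable record of configuration,
    seeds and library versions.  Rerunning with the same manifest
    reproduces every output byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        if config.cohort_path is not None:
            log.info("loading cohort from %s", config.cohort_path)
            cohort = load_feature_table(config.cohort_path)
        else:
            log.info("generating synthetic cohort (seed %d)", config.generator.seed)
            cohort = generate_cohort(config.generator)
            write_feature_table(cohort, out / "cohort.csv")

        stage = "split"
        train, test = stratified_split(
            cohort, SplitSpec(config.test_fraction, True, config.split_seed)
        )
        _dump(out / "split.json", {
            "train_ids": train.patient_ids,
            "test_ids": test.patient_ids,
            "test_label_counts": {str(k): v for k, v in sorted(test.label_counts().items())},
        })
        log.info("split: %d train / %d test patients", train.n_patients, test.n_patients)

        stage = "feature_selection"
        board = run_fs_mccv(train, config.fs_rounds, config.fs_seed, config.fs_settings())
        (out / "scoreboard.json").write_text(board.to_json() + "\n")

        stage = "signature"
        signature = select_signature(board, config.signature_size)
        _dump(out / "signature.json", {"signature": signature})
        log.info("signature: %s", ", ".join(signature))

        stage = "tuning"
        tuning = tune(train, signature, config.grid(), config.train_rounds, config.train_seed)
        tuning.curve.to_csv(out / "tuning_curve.csv", index=False)
        _dump(out / "best_config.json", tuning.best.to_dict())
        log.info("tuned config: %s", tuning.best)

        stage = "final_training"
        perf = run_training_mccv(
            train, signature, tuning.best, config.train_rounds, config.train_seed, test
        )
        _dump(out / "performance.json", perf.to_dict())
        perf.validation_rounds.to_csv(out / "validation_rounds.csv", index=False)
        perf.test_rounds.to_csv(out / "test_rounds.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "srmrad_version": __version__,
        "config": config.to_dict(),
        "seeds": {
            "base": config.seed,
            "split": config.split_seed,
            "feature_selection": config.fs_seed,
            "training": config.train_seed,
        },
        "versions": _library_versions(),
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    _dump(out / "manifest.json", manifest)

    result = PipelineResult(out, cohort, train, test, board, signature, tuning, perf)
    (out / "summary.txt").write_text(report_summary(out))
    return result


def _library_versions() -> dict:
    import pandas
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }


def replay_from_manifest(manifest_path, out_dir) -> PipelineResult:
    """Re-run a pipeline from its manifest; outputs are byte-identical."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = PipelineConfig.from_dict(manifest["config"])
    return run_pipeline(config, out_dir)


REQUIRED_ARTIFACTS = (
    "manifest.json",
    "split.json",
    "scoreboard.json",
    "signature.json",
    "tuning_curve.csv",
    "best_config.json",
    "performance.json",
)


def report_summary(run_dir) -> str:
    """Human-readable report of a completed run (idempotent to regenerate)."""
    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run in {run_dir}: missing {missing}")
    manifest = json.loads((run_dir / "manifest.json").read_text())
    split = json.loads((run_dir / "split.json").read_text())
    board = json.loads((run_dir / "scoreboard.json").read_text())
    signature = json.loads((run_dir / "signature.json").read_text())["signature"]
    best = json.loads((run_dir / "best_config.json").read_text())
    perf = json.loads((run_dir / "performance.json").read_text())
    cfg = manifest["config"]

    lines = []
    lines.append("Small-renal-mass radiomic signature — run summary")
    lines.append("=" * 52)
    lines.append(f"seed: {cfg['seed']}   rounds: FS={cfg['fs_rounds']} train={cfg['train_rounds']}")
    lines.append(
        "thresholds: redundancy |r| > {redundancy_threshold}, KW alpha = {alpha}, "
        "Spearman |rho| > {rho_threshold}".format(**cfg)
    )
    lines.append(f"test set: {len(split['test_ids'])} patients "
                 f"(malignant={split['test_label_counts'].get('1', 0)}, "
                 f"benign={split['test_label_counts'].get('0', 0)})")
    lines.append("")
    lines.append(f"Signature ({len(signature)} features, by cumulative score over "
                 f"{board['rounds']} rounds):")
    for name in signature:
        lines.append(f"  {name:<24s} score {board['scores'][name]:>4d}/{board['rounds']}"
                     f"   mean MW p {board['mean_p'][name]:.4f}")
    lines.append("")
    lines.append(f"Tuned model: {best['reduction'].upper()} d={best['d']}, k={best['k']}")
    lines.append("")
    lines.append("Performance (mean ± sd over rounds; malignant positive except F1):")
    lines.append(f"{'metric':<14s}{'validation':>18s}{'test':>18s}")
    for metric in ("roc_auc", "accuracy", "sensitivity", "specificity", "ppv", "npv",
                   "f1_minority"):
        v = perf["validation"][metric]
        t = perf.get("test", {}).get(metric)
        t_txt = f"{t['mean']:.2f} ± {t['sd']:.2f}" if t else "—"
        lines.append(f"{metric:<14s}{v['mean']:>11.2f} ± {v['sd']:.2f}{t_txt:>18s}")
    test_auc = perf.get("test", {}).get("roc_auc", {}).get("mean")
    if test_auc is not None and abs(test_auc - 0.5) < 0.1:
        lines.append("")
        lines.append(f"WARNING: mean test ROC-AUC = {test_auc:.2f} is close to chance (0.5); "
                     "the signature carries little or no outcome signal.")
    lines.append("")
    return "\n".join(lines) + "\n"
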