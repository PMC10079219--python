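"""YAML-driven experiment runs with a reproducibility manifest.

A run config declares a stage graph drawn from
``simulate -> preprocess -> split -> ablation -> benchmark -> pretrain``;
:func:`run_experiment` validates it up front, executes the stages in
order, writes every artifact as plain text, and records a
``manifest.json`` with the root seed, the per-stage substream seeds, the
package version, a snapshot of the resolved config, timestamps and
SHA-256 digests of each output. Re-running the same config with the same
root seed reproduces every artifact digest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .data import LabeledExpressionMatrix, read_matrix
from .evaluate import (
    BenchmarkPlan,
    run_ablation_comparison,
    run_benchmark,
    run_pretraining_comparison,
    write_results,
)
from .models import HyperparameterGrid, TrainConfig
from .preprocess import preprocess_pipeline, read_gene_lengths
from .rng import substream_seed
from .simulate import (
    SimulationConfig,
    StudyEffectConfig,
    simulate_linear_only,
    simulate_noise,
    simulate_study_structured,
    simulate_two_signal,
)
from .splits import group_kfold, pretrain_split

__all__ = ["run_experiment", "resolve_stages", "load_config"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "load", "preprocess", "split", "ablation", "benchmark", "pretrain")

_PRESETS = {
    "two-signal": simulate_two_signal,
    "linear-only": simulate_linear_only,
    "noise": simulate_noise,
}


def load_config(path) -> dict:
    with Path(path).open() as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("run config must be a YAML mapping")
    return config


def resolve_stages(config: dict) -> list[str]:
    """Validate the config's stage names and return them in run order."""
    declared = [k for k in config if k not in ("seed", "out_dir", "name")]
    for stage in declared:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r} in run config")
    ordered = [s for s in _STAGES if s in declared]
    if "simulate" not in ordered and "load" not in ordered:
        raise ValueError("config must declare a 'simulate' or 'load' stage")
    return ordered


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sim_config(section: dict, seed: int) -> SimulationConfig:
    keys = (
        "n_samples", "n_linear_features", "n_nonlinear_features", "n_noise_features",
        "linear_shift", "nonlinear_shift", "class_fraction",
    )
    return SimulationConfig(seed=seed, **{k: section[k] for k in keys if k in section})


def _train_config(section: dict) -> TrainConfig:
    keys = (
        "max_epochs", "learning_rate", "weight_decay", "batch_size",
        "early_stopping_patience", "gradient_clip_norm", "class_weighting",
    )
    return TrainConfig(**{k: section[k] for k in keys if k in section})


def _grid(section: dict) -> HyperparameterGrid | None:
    if "learning_rates" not in section and "weight_decays" not in section:
        return None
    return HyperparameterGrid(
        learning_rates=tuple(section.get("learning_rates", (1e-3,))),
        weight_decays=tuple(section.get("weight_decays", (0.0,))),
    )


def run_experiment(config, out_dir, dry_run: bool = False) -> dict:
    """Execute the declared stage graph; returns the run manifest.

    ``config`` is a mapping or a path to a YAML file. With ``dry_run``
    the config is validated and the resolved stage list returned without
    computing anything.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    stages = resolve_stages(config)
    root_seed = int(config.get("seed", 0))
    stage_seeds = {s: substream_seed(root_seed, f"stage/{s}") for s in stages}
    manifest = {
        "package": "linablate",
        "version": __version__,
        "root_seed": root_seed,
        "stage_seeds": stage_seeds,
        "stages": stages,
        "config": config,
        "started": None,
        "finished": None,
        "complete": False,
        "outputs": {},
    }
    if dry_run:
        return manifest

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest["started"] = datetime.now(timezone.utc).isoformat()

    def _record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _digest(path)}

    matrix: LabeledExpressionMatrix | None = None
    try:
        for stage in stages:
            section = config[stage] or {}
            seed = stage_seeds[stage]
            logger.info("stage %s (seed %d)", stage, seed)
            if stage == "simulate":
                preset = section.get("preset", "two-signal")
                sim = _sim_config(section, seed)
                if preset == "study-structured":
                    study = StudyEffectConfig(
                        n_studies=section.get("n_studies", 5),
                        study_shift_sd=section.get("study_shift_sd", 1.0),
                        label_study_association=section.get("label_study_association", 1.0),
                        seed=seed,
                    )
                    matrix = simulate_study_structured(sim, study)
                elif preset in _PRESETS:
                    matrix = _PRESETS[preset](sim)
                else:
                    raise ValueError(f"unknown simulation preset {preset!r}")
                matrix.to_tsv(out_dir / "dataset")
                _record("dataset", out_dir / "dataset.tsv")
            elif stage == "load":
                matrix = read_matrix(section["matrix"])
            elif stage == "preprocess":
                lengths = (
                    read_gene_lengths(section["lengths"]) if "lengths" in section else None
                )
                matrix = preprocess_pipeline(
                    matrix,
                    lengths,
                    tpm=section.get("tpm", False),
                    max_sparsity=section.get("max_sparsity", None),
                    scale=section.get("scale", False),
                    top_k=section.get("top_k", None),
                    split_safe=section.get("split_safe", False),
                )
            elif stage == "split":
                if section.get("kind", "kfold") == "pretrain":
                    plan = pretrain_split(
                        matrix, tuple(section.get("fractions", (0.4, 0.4, 0.2))), seed,
                        section.get("group", "study"),
                    )
                else:
                    plan = group_kfold(
                        matrix, section.get("k", 5), section.get("group", "study"), seed
                    )
                plan.to_tsv(out_dir / "split_plan.tsv")
                _record("split_plan", out_dir / "split_plan.tsv")
            elif stage == "ablation":
                records = run_ablation_comparison(
                    matrix,
                    section.get("models", list(_default_models())),
                    seeds=tuple(range(section.get("seeds", 1))),
                    val_fraction=section.get("val_fraction", 0.2),
                    ablation_modes=tuple(
                        m.replace("-", "_") for m in section.get("modes", ("none", "per_split"))
                    ),
                    grid=_grid(section),
                    train_config=_train_config(section),
                )
                write_results(records, out_dir / "ablation_results.tsv")
                _record("ablation_results", out_dir / "ablation_results.tsv")
            elif stage == "benchmark":
                plan = BenchmarkPlan(
                    k=section.get("k", 5),
                    split_mode=section.get("split", "study"),
                    seeds=tuple(range(section.get("seeds", 3))),
                    fractions=tuple(section.get("fractions", (1.0,))),
                    inner_k=section.get("inner_k", 2),
                )
                records, failures = run_benchmark(
                    matrix,
                    section.get("models", list(_default_models())),
                    plan,
                    ablation_mode=section.get("ablation", "none").replace("-", "_"),
                    grid=_grid(section),
                    train_config=_train_config(section),
                )
                write_results(records, out_dir / "benchmark_results.tsv")
                _record("benchmark_results", out_dir / "benchmark_results.tsv")
                if failures:
                    manifest["failures"] = failures
            elif stage == "pretrain":
                records = run_pretraining_comparison(
                    matrix,
                    section.get("models", list(_default_models())),
                    seeds=tuple(range(section.get("seeds", 5))),
                    fractions=tuple(section.get("fractions", (0.4, 0.4, 0.2))),
                    grouping_key=section.get("group", "study"),
                    train_config=_train_config(section),
                )
                write_results(records, out_dir / "pretrain_results.tsv")
                _record("pretrain_results", out_dir / "pretrain_results.tsv")
        manifest["complete"] = True
    finally:
        manifest["finished"] = datetime.now(timezone.utc).isoformat()
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _default_models() -> tuple:
    from .models import MODEL_KINDS

    return MODEL_KINDS
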