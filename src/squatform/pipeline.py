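"""End-to-end pipeline: simulate -> segment -> classify -> evaluate.

Holds the serializable run configuration and the orchestration that
ties the stages together, writing every intermediate artifact (trial
CSVs, repetition archive, feature table, report CSVs) under one output
directory.  Seeds are derived hierarchically from the master seed, so
any stage or subject can be reproduced in isolation and a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import evaluate, features, segment, simulate
from .core import PLACEMENT_ORDER, SensorPlacement

__all__ = ["PipelineConfig", "run_pipeline", "config_hash"]

log = logging.getLogger("squatform")


@dataclass
class PipelineConfig:
    """Every knob of an end-to-end run; YAML round-trip stable."""

    master_seed: int = 0
    n_subjects: int = 39
    sample_rate: float = 100.0
    reps_per_trial: int = 6
    out_len: int = 40
    n_folds: int = 10
    placements: list[str] = field(
        default_factory=lambda: [p.value for p in PLACEMENT_ORDER]
    )
    branches: list[str] = field(default_factory=lambda: ["cml", "dl"])
    combinations: str = "all"  # "all" = the study's 7; "single" = 1 per run
    cml_n_trees: int = 500
    dl_epochs: int = 500
    dl_batch_size: int = 64
    dl_eval_folds: int | None = None  # None = evaluate every fold

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash identifying the config that produced artifacts."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path
) -> list[evaluate.ClassificationReport]:
    """Execute all stages and write artifacts; returns the report set."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    config.to_yaml(out_dir / "config.yaml")
    (out_dir / "config_hash.txt").write_text(chash + "\n")

    placements = {SensorPlacement(p) for p in config.placements}

    log.info("simulate: %d subjects, seed %d", config.n_subjects, config.master_seed)
    try:
        trials = simulate.generate_dataset(
            n_subjects=config.n_subjects,
            reps_per_trial=config.reps_per_trial,
            sample_rate=config.sample_rate,
            master_seed=config.master_seed,
            placements=placements,
        )
    except Exception as e:  # pragma: no cover - error plumbing
        raise RuntimeError(f"stage simulate failed: {e}") from e
    trial_dir = out_dir / "trials"
    trial_dir.mkdir(exist_ok=True)
    for t in trials:
        simulate.write_trial_csv(
            t, trial_dir / f"trial_s{t.subject_id:03d}_{t.form.value}.csv"
        )
    log.info("simulate: wrote %d trials", len(trials))

    reps = []
    for t in trials:
        try:
            reps.extend(
                segment.segment_trial(
                    t, expected_count=config.reps_per_trial, out_len=config.out_len
                )
            )
        except Exception as e:
            raise RuntimeError(
                f"stage segment failed on subject {t.subject_id}, "
                f"form {t.form.value}: {e}"
            ) from e
    segment.write_repetition_archive(reps, out_dir / "repetitions")
    log.info("segment: %d repetitions", len(reps))

    active = [p for p in PLACEMENT_ORDER if p in placements]
    features.feature_table(reps, active).to_csv(
        out_dir / "features.csv", index=False
    )

    folds = evaluate.make_subject_folds(
        sorted({r.subject_id for r in reps}),
        n_folds=config.n_folds,
        rng_seed=simulate.derive_seed(config.master_seed, 0xF0) % 2**31,
    )
    combos = (
        evaluate.COMBINATIONS if config.combinations == "all" else (tuple(active),)
    )
    combos = tuple(
        c for c in combos if all(p in placements for p in c)
    )
    branch_options = {
        "cml": {"n_trees": config.cml_n_trees},
        "dl": {
            "epochs": config.dl_epochs,
            "batch_size": config.dl_batch_size,
        },
    }
    reports = []
    for combo in combos:
        for branch in config.branches:
            eval_folds = None
            if branch == "dl" and config.dl_eval_folds is not None:
                eval_folds = list(range(config.dl_eval_folds))
            log.info(
                "evaluate: %s on %s",
                branch,
                "+".join(p.value for p in combo),
            )
            reports.append(
                evaluate.cross_validate(
                    reps,
                    list(combo),
                    branch,
                    folds,
                    rng_seed=simulate.derive_seed(config.master_seed, 0xE1) % 2**31,
                    branch_options=branch_options.get(branch),
                    eval_folds=eval_folds,
                )
            )
    evaluate.write_reports(reports, out_dir / "reports")
    (out_dir / "reports" / "config_hash.txt").write_text(chash + "\n")
    log.info("evaluate: %d reports", len(reports))
    return reports
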