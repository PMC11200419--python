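"""End-to-end orchestration: phantom/loaded data -> preprocessing -> pairs ->
backend training -> anomaly maps -> threshold cross-validation -> report.

The pipeline is deliberately linear and deterministic: every stage consumes
the previous stage's output and a seed derived from the master seed, so a
run is reproducible from its configuration alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .anomaly import ThresholdCVResult, anomaly_map_for_study, threefold_threshold_cv
from .backends import CGANBackend, CGANConfig, DiffusionBackend, DiffusionConfig, OracleBackend
from .metrics import DEFAULT_EPSILON
from .phantom import PairedStudy, PhantomConfig, generate_dataset
from .preprocess import PreprocessConfig, preprocess_study
from .tasks import DEFAULT_FILL, TaskKind, build_training_set

__all__ = ["RunConfig", "TaskRunResult", "RunResult", "run_pipeline", "config_hash"]


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cgan: CGANConfig = field(default_factory=CGANConfig)
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    tasks: tuple[TaskKind, ...] = (TaskKind.SEQUENCE_TRANSLATION,)
    backend: str = "oracle"  # oracle | cgan | diffusion
    n_healthy: int = 4
    n_lesioned: int = 6
    score_against: str = "raters"  # raters | truth
    epsilon: float = DEFAULT_EPSILON
    fill_value: float = DEFAULT_FILL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("oracle", "cgan", "diffusion"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.score_against not in ("raters", "truth"):
            raise ValueError(f"score_against must be 'raters' or 'truth'")
        self.tasks = tuple(TaskKind(t) for t in self.tasks)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full configuration, for artifact provenance."""
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class TaskRunResult:
    task: TaskKind
    backend: str
    cv: ThresholdCVResult


@dataclass
class RunResult:
    config: RunConfig
    config_hash: str
    tasks: list[TaskRunResult]

    @property
    def report(self) -> pd.DataFrame:
        """Backend x task mean-DICE table plus per-fold detail rows."""
        rows = []
        for tr in self.tasks:
            for f in tr.cv.folds:
                rows.append({
                    "backend": tr.backend, "task": tr.task.value, "fold": f.fold_id,
                    "threshold": f.selection.chosen, "dice3d": f.test_dice,
                })
            rows.append({
                "backend": tr.backend, "task": tr.task.value, "fold": "mean",
                "threshold": float("nan"), "dice3d": tr.cv.mean_dice,
            })
        return pd.DataFrame(rows)


def _make_backend(name: str, config: RunConfig, studies: Sequence[PairedStudy],
                  task: TaskKind):
    if name == "oracle":
        return OracleBackend.from_studies(studies, task, config.fill_value)
    if name == "cgan":
        return CGANBackend(config.cgan)
    return DiffusionBackend(config.diffusion)


def run_pipeline(
    config: RunConfig,
    studies: Sequence[PairedStudy] | None = None,
) -> RunResult:
    """Run the full framework.

    If ``studies`` is None a phantom dataset is generated from
    ``config.phantom``; otherwise the given (raw, unpreprocessed) studies
    are used, with lesion-free studies forming the training set and
    lesion-bearing ones the test set.
    """
    if studies is None:
        studies = generate_dataset(config.phantom, config.n_healthy,
                                   config.n_lesioned, config.seed)
    pp = [preprocess_study(s, config.preprocess) for s in studies]
    train = [s for s in pp if not s.lesion_truth.data.any()]
    test = [s for s in pp if s.lesion_truth.data.any()]
    if config.backend != "oracle" and not train:
        raise ValueError("trainable backends need at least one healthy study")
    if len(test) < 3:
        raise ValueError("threshold cross-validation needs >= 3 lesioned test studies")

    results = []
    for ti, task in enumerate(config.tasks):
        backend = _make_backend(config.backend, config, test, task)
        if config.backend != "oracle":
            pairs = build_training_set(train, task, config.fill_value)
            backend.train(pairs, seed=config.seed + 1000 + ti)
        maps = [anomaly_map_for_study(s, backend, task, config.fill_value) for s in test]
        if config.score_against == "truth":
            refs = [[s.lesion_truth.data] for s in test]
        else:
            refs = [[m.data for m in s.rater_masks] for s in test]
        cv = threefold_threshold_cv(maps, refs, grid=None,
                                    seed=config.seed + 7, epsilon=config.epsilon)
        results.append(TaskRunResult(task=task, backend=config.backend, cv=cv))
    return RunResult(config=config, config_hash=config_hash(config), tasks=results)
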