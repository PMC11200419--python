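"""Anomaly maps and threshold selection.

The generative backend synthesizes a healthy version of each target slice;
the voxel-wise **positive part** of (real - synthesized) is the anomaly map.
The positive part, rather than the absolute difference, is used because the
lesions of interest are hyperintense in the target sequence — a synthesized
value *above* the real one is a synthesis artifact, not a lesion.

Postprocessing is deterministic: the bone mask zeroes anomalies outside
marrow (lesions cannot occur there), and a binarization threshold tau is
chosen by three-fold cross-validation over test volumes: for each fold, tau
is swept on the other two folds, the tau with the highest mean DICE against
the annotators is kept (ties -> smallest tau, the more sensitive choice),
and the held-out fold is scored at that tau.  The reported score is the
arithmetic mean of the three fold scores, which keeps the threshold from
overfitting the annotation set it is evaluated on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metrics import DEFAULT_EPSILON, dice3d
from .phantom import PairedStudy, Volume
from .tasks import TaskKind, build_pair

__all__ = [
    "AnomalyMap",
    "ThresholdSelection",
    "FoldResult",
    "ThresholdCVResult",
    "compute_anomaly_map",
    "apply_bone_mask",
    "binarize",
    "default_threshold_grid",
    "sweep_thresholds",
    "select_threshold",
    "threefold_threshold_cv",
    "anomaly_map_for_study",
]

N_GRID = 51  # candidate thresholds per sweep


@dataclass
class AnomalyMap:
    """Nonnegative voxel-wise anomaly intensities aligned to a target volume."""

    values: np.ndarray
    study_id: str = ""
    backend: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("anomaly values must be nonnegative")


@dataclass(frozen=True)
class ThresholdSelection:
    grid: np.ndarray
    mean_dice_per_candidate: np.ndarray
    chosen: float
    fold_id: int = -1


@dataclass(frozen=True)
class FoldResult:
    fold_id: int
    test_indices: tuple[int, ...]
    selection: ThresholdSelection
    test_dice: float


@dataclass(frozen=True)
class ThresholdCVResult:
    folds: tuple[FoldResult, ...]
    mean_dice: float


def compute_anomaly_map(real_target: Volume | np.ndarray, fake_target: Volume | np.ndarray,
                        **tags) -> AnomalyMap:
    """Positive part of (real - fake), voxel-wise."""
    real = real_target.data if isinstance(real_target, Volume) else np.asarray(real_target)
    fake = fake_target.data if isinstance(fake_target, Volume) else np.asarray(fake_target)
    if real.shape != fake.shape:
        raise ValueError(f"shape mismatch: real {real.shape} vs fake {fake.shape}")
    return AnomalyMap(np.maximum(real.astype(np.float64) - fake, 0.0), **tags)


def apply_bone_mask(amap: AnomalyMap, bone_mask: Volume | np.ndarray) -> AnomalyMap:
    """Zero every anomaly value outside the bone mask."""
    mask = bone_mask.data if isinstance(bone_mask, Volume) else np.asarray(bone_mask)
    if mask.shape != amap.values.shape:
        raise ValueError(f"shape mismatch: mask {mask.shape} vs map {amap.values.shape}")
    return AnomalyMap(amap.values * mask.astype(bool),
                      study_id=amap.study_id, backend=amap.backend, task=amap.task)


def binarize(amap: AnomalyMap, tau: float) -> np.ndarray:
    """Binary segmentation: voxel positive iff anomaly value > tau."""
    if not np.isfinite(tau) and not np.isposinf(tau):
        raise ValueError(f"tau must be finite or +inf, got {tau}")
    return (amap.values > tau).astype(np.uint8)


def default_threshold_grid(maps: Sequence[AnomalyMap], n: int = N_GRID) -> np.ndarray:
    """Evenly spaced candidates over the pooled anomaly-value range."""
    hi = max(float(m.values.max()) for m in maps)
    lo = min(float(m.values.min()) for m in maps)
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n)


def _score_at_tau(
    maps: Sequence[AnomalyMap],
    rater_masks_per_volume: Sequence[Sequence[np.ndarray]],
    tau: float,
    epsilon: float,
) -> float:
    """Volumes-then-raters aggregation: mean over volumes for each rater,
    then mean over raters (rater identity = position in each volume's list)."""
    n_raters = len(rater_masks_per_volume[0])
    if any(len(r) != n_raters for r in rater_masks_per_volume):
        raise ValueError("every volume must have the same number of rater masks")
    preds = [binarize(m, tau) for m in maps]
    per_rater = []
    for r in range(n_raters):
        scores = [
            dice3d(pred, np.asarray(masks[r]), epsilon)
            for pred, masks in zip(preds, rater_masks_per_volume)
        ]
        per_rater.append(np.mean(scores))
    return float(np.mean(per_rater))


def sweep_thresholds(
    maps: Sequence[AnomalyMap],
    rater_masks_per_volume: Sequence[Sequence[np.ndarray]],
    grid: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Mean DICE curve over the candidate grid (one value per tau)."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if len(maps) == 0 or len(maps) != len(rater_masks_per_volume):
        raise ValueError("need >=1 volume with aligned rater masks")
    return np.array([_score_at_tau(maps, rater_masks_per_volume, t, epsilon) for t in grid])


def select_threshold(grid: np.ndarray, curve: np.ndarray, fold_id: int = -1) -> ThresholdSelection:
    """Pick the tau with maximal mean DICE; ties break to the smallest tau."""
    grid = np.asarray(grid, dtype=np.float64)
    curve = np.asarray(curve, dtype=np.float64)
    if grid.shape != curve.shape or grid.size == 0:
        raise ValueError("grid and curve must be nonempty and aligned")
    idx = int(np.argmax(curve))  # first maximum = smallest tau on a sorted grid
    return ThresholdSelection(grid=grid, mean_dice_per_candidate=curve,
                              chosen=float(grid[idx]), fold_id=fold_id)


def threefold_threshold_cv(
    maps: Sequence[AnomalyMap],
    rater_masks_per_volume: Sequence[Sequence[np.ndarray]],
    grid: np.ndarray | None = None,
    seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
    n_folds: int = 3,
) -> ThresholdCVResult:
    """Three-fold cross-validated thresholding and scoring.

    Folds are assigned per volume (never per slice) by a seeded permutation.
    For each fold, the threshold is chosen on the other folds' volumes via
    :func:`sweep_thresholds`; if no grid is given, a fresh 51-point grid is
    built from the training folds' pooled anomaly range.  Returns per-fold
    selections and test scores plus their arithmetic mean.
    """
    n = len(maps)
    if n < n_folds:
        raise ValueError(f"need >= {n_folds} test volumes, got {n}")
    if len(rater_masks_per_volume) != n:
        raise ValueError("rater masks must align with anomaly maps")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [tuple(sorted(int(i) for i in order[k::n_folds])) for k in range(n_folds)]

    results = []
    for fold_id, test_idx in enumerate(folds):
        train_idx = [i for i in range(n) if i not in test_idx]
        train_maps = [maps[i] for i in train_idx]
        train_raters = [rater_masks_per_volume[i] for i in train_idx]
        fold_grid = np.asarray(grid) if grid is not None else default_threshold_grid(train_maps)
        curve = sweep_thresholds(train_maps, train_raters, fold_grid, epsilon)
        sel = select_threshold(fold_grid, curve, fold_id)
        test_maps = [maps[i] for i in test_idx]
        test_raters = [rater_masks_per_volume[i] for i in test_idx]
        score = _score_at_tau(test_maps, test_raters, sel.chosen, epsilon)
        results.append(FoldResult(fold_id, test_idx, sel, score))
    return ThresholdCVResult(tuple(results), float(np.mean([r.test_dice for r in results])))


def anomaly_map_for_study(
    study: PairedStudy,
    backend,
    task: TaskKind,
    fill_value: float = -1.0,
    mask_bone: bool = True,
) -> AnomalyMap:
    """Synthesize every slice of a (preprocessed) study with ``backend`` and
    assemble the bone-masked anomaly volume."""
    fake = np.empty_like(study.target.data, dtype=np.float64)
    real = np.empty_like(fake)
    for k in range(study.target.shape[0]):
        pair = build_pair(study, k, task, fill_value)
        fake[k] = backend.synthesize(pair)
        real[k] = pair.target
    amap = compute_anomaly_map(real, fake, study_id=study.study_id,
                               backend=type(backend).__name__, task=task.value)
    if mask_bone:
        amap = apply_bone_mask(amap, study.bone_mask)
    return amap
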