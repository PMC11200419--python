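"""Overlap metrics and rater-reliability protocols for lesion segmentation.

The Dice similarity coefficient (DICE) is the primary score used throughout:

    DICE = (2 TP + eps) / (2 TP + eps + FP + FN)

where ``eps`` is a small smoothing factor that stabilises the score when the
true-positive count is very low and prevents division by zero when both masks
are empty (in which case the smoothed score is exactly eps/eps = 1).  True
negatives are deliberately excluded: bone-marrow lesions occupy a tiny fraction
of a knee volume, so TN-inclusive scores such as accuracy saturate near 1
regardless of segmentation quality.

Volumes are compared either as a whole (3D DICE, one score per volume) or
slice by slice (2D DICE, averaged over slices).  The 2D average is sensitive
to how empty slices are handled: with eps > 0 an empty-vs-empty slice scores
1 and pulls the mean upward, while with eps = 0 it is undefined and must be
skipped.  Both behaviours are exposed via :class:`DiceConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "DiceConfig",
    "EmptySlicePolicy",
    "SliceScope",
    "confusion",
    "dice",
    "accuracy",
    "dice3d",
    "dice2d",
    "evaluate_model",
    "reliability_report",
]

DEFAULT_EPSILON = 1e-6


class EmptySlicePolicy(str, Enum):
    """How 2D averaging treats slices where prediction and truth are both empty
    and eps = 0 leaves the score undefined."""

    INCLUDE_AS_ONE = "include_as_one"
    SKIP = "skip"


class SliceScope(str, Enum):
    """Which slices enter the 2D average: every slice, or only slices whose
    reference mask contains at least one lesion voxel."""

    ALL_SLICES = "all_slices"
    LESION_SLICES = "lesion_slices"


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-wise binary confusion tallies."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiceConfig:
    """Smoothing and empty-slice handling for DICE evaluation."""

    epsilon: float = DEFAULT_EPSILON
    empty_slice_policy: EmptySlicePolicy = EmptySlicePolicy.INCLUDE_AS_ONE

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/FN/TN between two binary masks of identical shape."""
    pred = _as_bool(pred)
    truth = _as_bool(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(pred.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dice(counts: ConfusionCounts, epsilon: float = DEFAULT_EPSILON) -> float:
    """Smoothed DICE from confusion counts.

    With ``epsilon = 0`` and TP = FP = FN = 0 the score is undefined and a
    ``ZeroDivisionError`` is raised; callers doing 2D slice averaging catch
    this and apply their empty-slice policy.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    num = 2.0 * counts.tp + epsilon
    den = 2.0 * counts.tp + epsilon + counts.fp + counts.fn
    if den == 0.0:
        raise ZeroDivisionError(
            "DICE undefined: TP=FP=FN=0 with epsilon=0 (empty masks, no smoothing)"
        )
    return num / den


def accuracy(counts: ConfusionCounts) -> float:
    """(TP+TN) / N.  Skewed toward 1 when true negatives dominate."""
    if counts.total == 0:
        raise ValueError("accuracy undefined on zero voxels")
    return (counts.tp + counts.tn) / counts.total


def dice3d(pred: np.ndarray, truth: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> float:
    """Single DICE score over all voxels of a volume."""
    return dice(confusion(pred, truth), epsilon)


def dice2d(
    pred: np.ndarray,
    truth: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    policy: EmptySlicePolicy = EmptySlicePolicy.INCLUDE_AS_ONE,
    scope: SliceScope = SliceScope.ALL_SLICES,
    axis: int = 0,
) -> float:
    """Mean per-slice DICE along ``axis``.

    ``scope=LESION_SLICES`` drops slices whose *truth* mask is empty before
    averaging.  ``policy`` only matters when ``epsilon == 0`` and a retained
    slice has TP = FP = FN = 0.
    """
    pred = _as_bool(pred)
    truth = _as_bool(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    pred = np.moveaxis(pred, axis, 0)
    truth = np.moveaxis(truth, axis, 0)

    scores: list[float] = []
    for p_slice, t_slice in zip(pred, truth):
        if scope is SliceScope.LESION_SLICES and not t_slice.any():
            continue
        counts = confusion(p_slice, t_slice)
        try:
            scores.append(dice(counts, epsilon))
        except ZeroDivisionError:
            if policy is EmptySlicePolicy.INCLUDE_AS_ONE:
                scores.append(1.0)
            # SKIP: slice ignored
    if not scores:
        if scope is SliceScope.LESION_SLICES:
            raise ValueError("no lesion-bearing slices in scope")
        raise ValueError("no slices with a defined DICE score")
    return float(np.mean(scores))


def evaluate_model(
    pred_volumes: Mapping[str, np.ndarray],
    rater_masks: Mapping[str, Mapping[str, np.ndarray]],
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Score predicted segmentations against every rater's annotations.

    3D DICE is computed per (volume, rater), averaged across volumes for each
    rater, then those per-rater means are averaged across raters — volumes
    first, raters second.  ``rater_masks`` maps rater id -> {volume id ->
    mask}; every prediction must be covered by every rater.

    Returns a table with one row per rater plus an ``overall`` row.
    """
    if not pred_volumes:
        raise ValueError("no predicted volumes given")
    if not rater_masks:
        raise ValueError("no rater masks given")
    rows = []
    per_rater_means = []
    for rater_id, masks in rater_masks.items():
        missing = set(pred_volumes) - set(masks)
        if missing:
            raise ValueError(f"rater {rater_id!r} missing masks for volumes {sorted(missing)}")
        scores = [
            dice3d(pred_volumes[vid], masks[vid], epsilon) for vid in sorted(pred_volumes)
        ]
        mean = float(np.mean(scores))
        per_rater_means.append(mean)
        rows.append({"rater": rater_id, "n_volumes": len(scores), "dice3d_mean": mean})
    rows.append(
        {
            "rater": "overall",
            "n_volumes": len(pred_volumes),
            "dice3d_mean": float(np.mean(per_rater_means)),
        }
    )
    return pd.DataFrame(rows)


def _agreement_row(
    sets_a: Mapping[str, np.ndarray],
    sets_b: Mapping[str, np.ndarray],
    epsilon: float,
    policy: EmptySlicePolicy,
) -> dict[str, float]:
    vids = sorted(set(sets_a) & set(sets_b))
    if not vids:
        raise ValueError("no common volumes between annotation sets")
    d3, d2_all, d2_lesion = [], [], []
    for vid in vids:
        a, b = sets_a[vid], sets_b[vid]
        d3.append(dice3d(a, b, epsilon))
        d2_all.append(dice2d(a, b, epsilon, policy, SliceScope.ALL_SLICES))
        try:
            d2_lesion.append(dice2d(a, b, epsilon, policy, SliceScope.LESION_SLICES))
        except ValueError:
            pass  # volume with no annotated lesion slices contributes nothing
    return {
        "dice3d": float(np.mean(d3)),
        "dice2d_all_slices": float(np.mean(d2_all)),
        "dice2d_lesion_slices": float(np.mean(d2_lesion)) if d2_lesion else float("nan"),
        "n_volumes": len(vids),
    }


def reliability_report(
    rater_sets: Mapping[str, Sequence[Mapping[str, np.ndarray]]],
    epsilon: float = DEFAULT_EPSILON,
    policy: EmptySlicePolicy = EmptySlicePolicy.INCLUDE_AS_ONE,
) -> pd.DataFrame:
    """Intra-/inter-rater agreement table.

    ``rater_sets`` maps rater id -> list of annotation sets, each set being a
    {volume id -> binary mask} mapping.  A rater with two or more sets yields
    intra-rater rows (agreement between their own repeat annotations); every
    pair of distinct raters yields an inter-rater row (first set of each).
    Columns: 3D DICE, 2D DICE over all slices, 2D DICE over lesion slices —
    each averaged over the common volumes.
    """
    raters = sorted(rater_sets)
    if len(raters) < 2 and not any(len(rater_sets[r]) >= 2 for r in raters):
        raise ValueError("need >=2 raters or a rater with repeat annotations")
    rows = []
    for rid in raters:
        sets = rater_sets[rid]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                row = {"kind": "intra", "raters": f"{rid}(set{i})/{rid}(set{j})"}
                row.update(_agreement_row(sets[i], sets[j], epsilon, policy))
                rows.append(row)
    for i in range(len(raters)):
        for j in range(i + 1, len(raters)):
            ra, rb = raters[i], raters[j]
            row = {"kind": "inter", "raters": f"{ra}/{rb}"}
            row.update(_agreement_row(rater_sets[ra][0], rater_sets[rb][0], epsilon, policy))
            rows.append(row)
    if not rows:
        raise ValueError("no agreement pairs could be formed")
    return pd.DataFrame(rows)
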