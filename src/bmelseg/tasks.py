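"""Construction of 2D (conditioning, target) pairs for the three tasks.

A conditional generative model is trained to synthesize a healthy target-
sequence slice x from a conditioning image c.  Three ways of building c from
a co-registered study are supported:

* **sequence translation** — c is the conditioning-sequence slice (lesions
  near-isointense there), x the target-sequence slice;
* **bone inpainting** — c is the target slice with the bone region blanked
  out, x the full target slice; the model learns to inpaint healthy marrow;
* **bone translation** — sequence translation restricted to bone: non-bone
  voxels of both c and x are blanked.

Blanked voxels are set to ``fill_value`` (default -1, the tanh/air level).
Training sets are built from healthy studies only — the entire framework
rests on the generator never having seen a lesion.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .phantom import PairedStudy

__all__ = ["TaskKind", "ConditioningPair", "build_pair", "build_training_set", "DEFAULT_FILL"]

DEFAULT_FILL = -1.0


class TaskKind(str, Enum):
    SEQUENCE_TRANSLATION = "sequence_translation"
    BONE_INPAINTING = "bone_inpainting"
    BONE_TRANSLATION = "bone_translation"


@dataclass(frozen=True)
class ConditioningPair:
    """One 2D training/inference example."""

    conditioning: np.ndarray
    target: np.ndarray
    bone_mask_slice: np.ndarray
    study_id: str
    slice_index: int
    task: TaskKind

    def __post_init__(self) -> None:
        if not (self.conditioning.shape == self.target.shape == self.bone_mask_slice.shape):
            raise ValueError("conditioning, target and bone mask slices must share shape")


def build_pair(
    study: PairedStudy,
    slice_index: int,
    task: TaskKind,
    fill_value: float = DEFAULT_FILL,
    use_healthy_target: bool = False,
) -> ConditioningPair:
    """Build the (c, x) pair for one slice of a (preprocessed) study.

    ``use_healthy_target`` substitutes the lesion-free reference volume as
    the supervision target; training-set construction uses it never (healthy
    studies are required instead), but the oracle backend's lookup is built
    from it.
    """
    n_slices = study.target.shape[0]
    if not 0 <= slice_index < n_slices:
        raise IndexError(f"slice index {slice_index} out of range [0, {n_slices})")
    target_vol = study.healthy_target if use_healthy_target else study.target
    x = np.array(target_vol.data[slice_index], dtype=np.float64)
    cond = np.array(study.conditioning.data[slice_index], dtype=np.float64)
    bone = study.bone_mask.data[slice_index].astype(bool)

    if task is TaskKind.SEQUENCE_TRANSLATION:
        c = cond
    elif task is TaskKind.BONE_INPAINTING:
        c = x.copy()
        c[bone] = fill_value
    elif task is TaskKind.BONE_TRANSLATION:
        c = cond.copy()
        c[~bone] = fill_value
        x = x.copy()
        x[~bone] = fill_value
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown task {task!r}")
    return ConditioningPair(
        conditioning=c,
        target=x,
        bone_mask_slice=bone.astype(np.uint8),
        study_id=study.study_id,
        slice_index=slice_index,
        task=task,
    )


def build_training_set(
    studies: Sequence[PairedStudy],
    task: TaskKind,
    fill_value: float = DEFAULT_FILL,
) -> list[ConditioningPair]:
    """One pair per slice per healthy study, ordered by (study_id, slice).

    Any study with a nonempty ground-truth lesion mask is rejected: training
    on lesioned data would teach the generator to reproduce lesions and
    silence the anomaly signal.
    """
    for study in studies:
        if study.lesion_truth.data.any():
            raise ValueError(
                f"study {study.study_id!r} contains lesion voxels; "
                "the training set must be lesion-free"
            )
    pairs: list[ConditioningPair] = []
    for study in sorted(studies, key=lambda s: s.study_id):
        for k in range(study.target.shape[0]):
            pairs.append(build_pair(study, k, task, fill_value))
    return pairs
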