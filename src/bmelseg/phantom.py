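"""Synthetic paired-sequence knee phantom with bone-marrow-edema-like lesions.

Real studies of this kind pair two co-registered MRI sequences of the same
knee: a fluid-sensitive target sequence (TSE-like) in which marrow lesions are
hyperintense against dark, fat-suppressed healthy marrow, and a conditioning
sequence (DESS-like) in which the same lesions are nearly isointense.  The
phantom reproduces exactly the structure the segmentation framework exploits:

* two smooth bone components per volume (femur/tibia analogues) given by a
  perturbed-ellipsoid mask;
* zero or more lesions confined to bone marrow, built as Gaussian-blurred
  ellipsoids so their boundaries are diffuse; the binary ground truth is the
  half-maximum level set of the blurred field;
* a strong additive lesion contrast in the target sequence and a near-zero
  one in the conditioning sequence;
* per-volume multiplicative intensity scales emulating the mixed bit depths
  seen across scanners, which the preprocessing stage must absorb;
* simulated annotators who disagree with the truth through a shifted
  intensity threshold, dilated/eroded extent, and occasional missed lesions —
  the three disagreement modes seen between human raters.

Every output is a deterministic function of (config, seed).  A
``healthy_target`` volume — the target sequence with the lesion signal
removed but identical noise — is kept as the oracle reference for a perfect
pseudo-healthy generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "RaterJitter",
    "PhantomConfig",
    "Volume",
    "PairedStudy",
    "generate_study",
    "generate_dataset",
    "simulate_rater",
]

_MIN_DIM = 8
_FIELD_SUPPORT_CUTOFF = 0.05  # blurred lesion field is truncated below this


@dataclass(frozen=True)
class RaterJitter:
    """Annotation-disagreement magnitudes for a simulated rater.

    threshold_sd: s.d. of the shift applied to the half-maximum intensity
    threshold (the dominant disagreement mode between human annotators);
    morph_radius: maximal radius of random dilation/erosion of the region of
    interest (extent disagreement); p_miss: probability a lesion component is
    not annotated at all (presence disagreement).
    """

    threshold_sd: float = 0.08
    morph_radius: int = 1
    p_miss: float = 0.1

    def __post_init__(self) -> None:
        if self.threshold_sd < 0 or self.morph_radius < 0 or not 0 <= self.p_miss <= 1:
            raise ValueError(f"invalid rater jitter: {self}")

    @property
    def is_zero(self) -> bool:
        return self.threshold_sd == 0 and self.morph_radius == 0 and self.p_miss == 0


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (16, 64, 64)
    bone_fraction_range: tuple[float, float] = (0.10, 0.18)
    n_lesions_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (3.5, 6.0)
    boundary_blur_sigma: float = 1.2
    target_lesion_contrast: float = 0.5
    conditioning_lesion_contrast: float = 0.02
    noise_sd: float = 0.02
    intensity_scale_range: tuple[float, float] = (0.5, 2.0)
    n_raters: int = 2
    rater_jitter: RaterJitter = field(default_factory=RaterJitter)

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(d) != d or d <= 0 for d in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive integers, got {self.grid_shape}")
        for name in (
            "bone_fraction_range",
            "n_lesions_range",
            "lesion_radius_range",
            "intensity_scale_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy low <= high, got ({lo}, {hi})")
        lo, hi = self.bone_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError(f"bone_fraction_range must lie in (0,1), got ({lo}, {hi})")
        if self.n_lesions_range[0] < 0:
            raise ValueError("n_lesions_range must be nonnegative")
        if self.boundary_blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("boundary_blur_sigma and noise_sd must be nonnegative")
        if self.target_lesion_contrast <= 0:
            raise ValueError("target_lesion_contrast must be positive")
        if not 0 <= self.conditioning_lesion_contrast <= self.target_lesion_contrast:
            raise ValueError(
                "conditioning_lesion_contrast must be in [0, target_lesion_contrast] "
                "(lesions are near-isointense in the conditioning sequence)"
            )
        if self.n_raters < 1:
            raise ValueError("n_raters must be positive")


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing (mm) and an orientation tag."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (3.0, 0.4, 0.4)
    orientation: str = "sagittal"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=np.asarray(data))


@dataclass
class PairedStudy:
    """One subject: co-registered conditioning/target volumes, bone mask,
    generator ground truth, simulated rater annotations, and the lesion-free
    ``healthy_target`` oracle reference.  ``lesion_field`` is the smooth
    pre-threshold lesion intensity field (compact support; truth is its
    half-maximum level set), kept so rater simulation can re-threshold it."""

    conditioning: Volume
    target: Volume
    bone_mask: Volume
    lesion_truth: Volume
    rater_masks: list[Volume]
    healthy_target: Volume
    lesion_field: Volume
    study_id: str
    seed: int

    @property
    def shape(self) -> tuple[int, ...]:
        return self.target.shape


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean unit-amplitude smooth random field (texture/inhomogeneity)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _bone_mask(rng: np.random.Generator, shape, fraction_range) -> np.ndarray:
    """Two perturbed ellipsoids stacked in-plane, sized to a drawn fraction."""
    s, r, c = shape
    frac = rng.uniform(*fraction_range)
    zz, yy, xx = np.meshgrid(
        np.arange(s), np.arange(r), np.arange(c), indexing="ij"
    )
    mask = np.zeros(shape, dtype=bool)
    # femur analogue in the upper half, tibia analogue in the lower half
    for row_center_frac in (0.28, 0.72):
        az = 0.42 * s * rng.uniform(0.9, 1.1)
        target_vox = frac / 2 * s * r * c
        ar = ax = float(np.sqrt(3.0 * target_vox / (4.0 * np.pi * az)))
        cz = s / 2 + rng.uniform(-0.05, 0.05) * s
        cy = row_center_frac * r + rng.uniform(-0.03, 0.03) * r
        cx = c / 2 + rng.uniform(-0.08, 0.08) * c
        f = 1.0 - ((zz - cz) / az) ** 2 - ((yy - cy) / ar) ** 2 - ((xx - cx) / ax) ** 2
        f += 0.18 * _smooth_field(rng, shape, sigma=(1.5, 6.0, 6.0))
        mask |= f > 0
    return mask


def _place_lesions(
    rng: np.random.Generator, config: PhantomConfig, bone: np.ndarray
) -> np.ndarray:
    """Blurred-ellipsoid lesion field confined to bone; max value ~1."""
    shape = bone.shape
    n = int(rng.integers(config.n_lesions_range[0], config.n_lesions_range[1] + 1))
    if n == 0:
        return np.zeros(shape, dtype=np.float64)
    dist = ndimage.distance_transform_edt(bone)
    indicator = np.zeros(shape, dtype=np.float64)
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    for _ in range(n):
        radius = rng.uniform(*config.lesion_radius_range)
        deep = np.argwhere(dist >= 0.6 * radius)
        if len(deep) == 0:
            deep = np.argwhere(dist == dist.max())
        cz, cy, cx = deep[rng.integers(len(deep))]
        # slices are thick relative to in-plane voxels: flatten along axis 0
        az = max(1.2, 0.45 * radius) * rng.uniform(0.8, 1.2)
        ay = radius * rng.uniform(0.7, 1.3)
        ax = radius * rng.uniform(0.7, 1.3)
        e = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        indicator = np.maximum(indicator, (e <= 1.0).astype(np.float64))
    # diffuse boundaries are an in-plane feature: slices are thick relative to
    # in-plane voxels, so through-slice blur is kept much smaller
    fld = ndimage.gaussian_filter(
        indicator,
        sigma=(0.3 * config.boundary_blur_sigma,
               config.boundary_blur_sigma,
               config.boundary_blur_sigma),
    )
    if fld.max() > 0:
        fld = fld / fld.max()
    # plateau-preserving clamp: lesion cores carry the full configured
    # contrast while the boundary ramp stays diffuse
    fld = np.minimum(1.0, 1.6 * fld)
    fld[fld < _FIELD_SUPPORT_CUTOFF] = 0.0  # compact support
    fld *= bone  # lesions exist only in marrow
    return fld


def simulate_rater(
    study: PairedStudy, rater_params: RaterJitter, seed: int
) -> Volume:
    """One simulated expert annotation of ``study``'s lesions.

    The rater re-thresholds the smooth lesion field at a shifted level
    (threshold disagreement), randomly dilates or erodes the result (extent
    disagreement), and may drop whole lesion components (presence
    disagreement).  With all jitter at zero the annotation equals the ground
    truth exactly.  The returned mask is always confined to bone.
    """
    rng = np.random.default_rng(seed)
    fld = study.lesion_field.data
    bone = study.bone_mask.data.astype(bool)

    thr = 0.5 + float(rng.normal(0.0, rater_params.threshold_sd)) if rater_params.threshold_sd else 0.5
    thr = float(np.clip(thr, 1.5 * _FIELD_SUPPORT_CUTOFF, 0.95))
    mask = fld >= thr

    if rater_params.morph_radius > 0:
        r = int(rng.integers(-rater_params.morph_radius, rater_params.morph_radius + 1))
        if r > 0:
            mask = ndimage.binary_dilation(mask, iterations=r)
        elif r < 0:
            mask = ndimage.binary_erosion(mask, iterations=-r)

    if rater_params.p_miss > 0 and mask.any():
        labels, n_comp = ndimage.label(mask)
        for comp in range(1, n_comp + 1):
            if rng.uniform() < rater_params.p_miss:
                mask[labels == comp] = False

    mask &= bone
    return Volume(mask.astype(np.uint8), study.bone_mask.spacing, study.bone_mask.orientation)


def generate_study(
    config: PhantomConfig,
    seed: int,
    with_lesions: bool = True,
    study_id: str | None = None,
) -> PairedStudy:
    """Generate one paired study deterministically from (config, seed)."""
    if any(d < _MIN_DIM for d in config.grid_shape):
        raise ValueError(
            f"degenerate grid {config.grid_shape}: every dimension must be >= {_MIN_DIM}"
        )
    rng = np.random.default_rng(seed)
    shape = tuple(int(d) for d in config.grid_shape)

    bone = _bone_mask(rng, shape, config.bone_fraction_range)

    if with_lesions and config.n_lesions_range[1] > 0:
        fld = _place_lesions(rng, config, bone)
    else:
        fld = np.zeros(shape, dtype=np.float64)
    truth = fld >= 0.5

    texture = _smooth_field(rng, shape, sigma=(1.0, 4.0, 4.0))
    # conditioning sequence: bright-ish bone, lesions nearly invisible
    conditioning = 0.35 + 0.05 * texture + 0.20 * bone
    conditioning = conditioning + config.conditioning_lesion_contrast * fld
    # target sequence: fat-suppressed dark marrow, hyperintense lesions
    healthy_target = 0.45 + 0.05 * texture - 0.25 * bone

    if config.noise_sd > 0:
        conditioning = conditioning + rng.normal(0.0, config.noise_sd, shape)
        healthy_target = healthy_target + rng.normal(0.0, config.noise_sd, shape)
    target = healthy_target + config.target_lesion_contrast * fld

    # independent per-sequence intensity scales (mixed bit-depth emulation);
    # target and its healthy reference share one scale so they stay comparable
    s_cond = rng.uniform(*config.intensity_scale_range)
    s_tgt = rng.uniform(*config.intensity_scale_range)
    conditioning = conditioning * s_cond
    target = target * s_tgt
    healthy_target = healthy_target * s_tgt

    sid = study_id if study_id is not None else f"phantom-{seed:010d}"
    study = PairedStudy(
        conditioning=Volume(conditioning),
        target=Volume(target),
        bone_mask=Volume(bone.astype(np.uint8)),
        lesion_truth=Volume(truth.astype(np.uint8)),
        rater_masks=[],
        healthy_target=Volume(healthy_target),
        lesion_field=Volume(fld),
        study_id=sid,
        seed=int(seed),
    )
    rater_seeds = rng.integers(0, 2**31 - 1, size=config.n_raters)
    study.rater_masks = [
        simulate_rater(study, config.rater_jitter, int(s)) for s in rater_seeds
    ]
    return study


def generate_dataset(
    config: PhantomConfig,
    n_healthy: int,
    n_lesioned: int,
    seed: int,
    max_retries: int = 10,
) -> list[PairedStudy]:
    """Generate ``n_healthy`` lesion-free plus ``n_lesioned`` lesioned studies.

    Per-study seeds are drawn once from the master seed, so the dataset is
    reproducible and each study is independently regenerable from its own
    recorded seed.  Lesioned studies are guaranteed at least one ground-truth
    lesion voxel (regenerated with a fresh sub-seed in the rare case blurring
    erases a tiny lesion)."""
    if n_healthy < 0 or n_lesioned < 0:
        raise ValueError("study counts must be nonnegative")
    master = np.random.default_rng(seed)
    total = n_healthy + n_lesioned
    study_seeds = master.integers(0, 2**31 - 1, size=total)
    retry_seeds = master.integers(0, 2**31 - 1, size=max(1, n_lesioned) * max_retries)
    studies: list[PairedStudy] = []
    retry_idx = 0
    for i in range(n_healthy):
        studies.append(
            generate_study(config, int(study_seeds[i]), with_lesions=False,
                           study_id=f"healthy-{i:03d}")
        )
    lesion_cfg = config
    if config.n_lesions_range[0] == 0:
        lesion_cfg = replace(config, n_lesions_range=(1, max(1, config.n_lesions_range[1])))
    for i in range(n_lesioned):
        s = int(study_seeds[n_healthy + i])
        study = generate_study(lesion_cfg, s, with_lesions=True, study_id=f"lesioned-{i:03d}")
        tries = 0
        while not study.lesion_truth.data.any() and tries < max_retries:
            s = int(retry_seeds[retry_idx])
            retry_idx += 1
            tries += 1
            study = generate_study(lesion_cfg, s, with_lesions=True,
                                   study_id=f"lesioned-{i:03d}")
        if not study.lesion_truth.data.any():
            raise RuntimeError(f"could not place a lesion in study lesioned-{i:03d}")
        studies.append(study)
    return studies
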