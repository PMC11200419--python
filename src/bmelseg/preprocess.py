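"""Intensity and spatial standardisation of paired MRI volumes.

Volumes arriving from different scanners differ in bit depth and intensity
scale, so each volume is standardised independently before any model sees it:

1. **scale** — divide by the volume's maximum absolute intensity, collapsing
   arbitrary per-scanner scales to a common order of magnitude;
2. **quantile clip** — clip to the 0.001 / 0.999 empirical quantiles of the
   whole volume (all slices jointly), limiting extreme values, especially on
   the bright end;
3. **rescale** — affinely map the post-clip [min, max] onto [-1, 1], the
   range of the tanh output activation used by the generative backends;
4. **center crop** — optionally crop each slice in-plane, with the window
   centred (floor offset on odd remainders).

Quantiles use outward-rounding order statistics (the ``lower`` method for the
low quantile, ``higher`` for the high one): the clip bounds are then actual
voxel values, clipping is conservative, and the whole pipeline is exactly
idempotent on its own output.  Fitted parameters are returned so a companion
volume (e.g. a pseudo-healthy reference) can be carried into exactly the
same intensity frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phantom import PairedStudy, Volume

__all__ = [
    "PreprocessConfig",
    "PreprocessParams",
    "quantile_clip",
    "rescale_to_range",
    "center_crop",
    "fit_intensity_params",
    "apply_intensity_params",
    "preprocess_volume",
    "preprocess_study",
    "histogram_report",
]


@dataclass(frozen=True)
class PreprocessConfig:
    q_low: float = 0.001
    q_high: float = 0.999
    out_range: tuple[float, float] = (-1.0, 1.0)
    crop_shape: tuple[int, int] | None = None  # (rows, cols); None = no crop

    def __post_init__(self) -> None:
        if not 0 <= self.q_low < self.q_high <= 1:
            raise ValueError(f"need 0 <= q_low < q_high <= 1, got ({self.q_low}, {self.q_high})")
        if self.out_range[0] >= self.out_range[1]:
            raise ValueError(f"out_range must be increasing, got {self.out_range}")


@dataclass(frozen=True)
class PreprocessParams:
    """Fitted per-volume intensity transform: x -> affine(clip(x / scale))."""

    scale: float
    clip_low: float
    clip_high: float


def quantile_clip(volume: Volume, config: PreprocessConfig = PreprocessConfig()) -> Volume:
    """Clip a volume to its own (q_low, q_high) empirical quantiles."""
    data = volume.data
    if data.size == 0:
        raise ValueError("empty volume")
    lo = np.quantile(data, config.q_low, method="lower")
    hi = np.quantile(data, config.q_high, method="higher")
    return volume.with_data(np.clip(data, lo, hi))


def rescale_to_range(volume: Volume, config: PreprocessConfig = PreprocessConfig()) -> Volume:
    """Affine map sending the volume's [min, max] onto ``config.out_range``."""
    data = volume.data.astype(np.float64)
    vmin, vmax = float(data.min()), float(data.max())
    if vmax <= vmin:
        raise ValueError("cannot rescale a constant volume (degenerate intensity range)")
    lo, hi = config.out_range
    return volume.with_data(lo + (data - vmin) * (hi - lo) / (vmax - vmin))


def center_crop(volume: Volume, crop_shape: tuple[int, int]) -> Volume:
    """Crop each slice in-plane to ``crop_shape``, centred with floor offsets."""
    rows, cols = volume.data.shape[1], volume.data.shape[2]
    cr, cc = crop_shape
    if cr > rows or cc > cols:
        raise ValueError(f"crop {crop_shape} exceeds in-plane shape ({rows}, {cols})")
    r0 = (rows - cr) // 2
    c0 = (cols - cc) // 2
    return volume.with_data(volume.data[:, r0 : r0 + cr, c0 : c0 + cc])


def fit_intensity_params(volume: Volume, config: PreprocessConfig = PreprocessConfig()) -> PreprocessParams:
    data = volume.data.astype(np.float64)
    if data.size == 0:
        raise ValueError("empty volume")
    scale = float(np.abs(data).max())
    if scale == 0:
        scale = 1.0
    scaled = data / scale
    lo = np.quantile(scaled, config.q_low, method="lower")
    hi = np.quantile(scaled, config.q_high, method="higher")
    return PreprocessParams(scale=scale, clip_low=float(lo), clip_high=float(hi))


def apply_intensity_params(
    volume: Volume, params: PreprocessParams, config: PreprocessConfig = PreprocessConfig()
) -> Volume:
    """Apply a fitted scale-clip-rescale transform (no crop)."""
    data = volume.data.astype(np.float64) / params.scale
    data = np.clip(data, params.clip_low, params.clip_high)
    if params.clip_high <= params.clip_low:
        raise ValueError("cannot rescale a constant volume (degenerate intensity range)")
    lo, hi = config.out_range
    data = lo + (data - params.clip_low) * (hi - lo) / (params.clip_high - params.clip_low)
    return volume.with_data(data)


def preprocess_volume(
    volume: Volume, config: PreprocessConfig = PreprocessConfig()
) -> tuple[Volume, PreprocessParams]:
    """Full pipeline scale -> clip -> rescale -> crop for one volume."""
    params = fit_intensity_params(volume, config)
    out = apply_intensity_params(volume, params, config)
    if config.crop_shape is not None:
        out = center_crop(out, config.crop_shape)
    return out, params


def preprocess_study(study: PairedStudy, config: PreprocessConfig = PreprocessConfig()) -> PairedStudy:
    """Standardise a paired study.

    The conditioning and target volumes each get their own fitted intensity
    transform; the healthy reference is carried with the *target's* transform
    so that "healthy equals target outside lesions" survives preprocessing.
    Masks and the lesion field are only cropped.
    """
    cond, _ = preprocess_volume(study.conditioning, config)
    tgt_params = fit_intensity_params(study.target, config)
    tgt = apply_intensity_params(study.target, tgt_params, config)
    healthy = apply_intensity_params(study.healthy_target, tgt_params, config)

    def _spatial(v: Volume) -> Volume:
        return center_crop(v, config.crop_shape) if config.crop_shape is not None else v

    tgt = _spatial(tgt)
    healthy = _spatial(healthy)
    return PairedStudy(
        conditioning=cond,
        target=tgt,
        bone_mask=_spatial(study.bone_mask),
        lesion_truth=_spatial(study.lesion_truth),
        rater_masks=[_spatial(m) for m in study.rater_masks],
        healthy_target=healthy,
        lesion_field=_spatial(study.lesion_field),
        study_id=study.study_id,
        seed=study.seed,
    )


def histogram_report(
    volumes: Mapping[str, Volume],
    region_masks: Mapping[str, Mapping[str, Volume]] | None = None,
    n_bins: int = 64,
    quantiles: Sequence[float] = (0.001, 0.25, 0.5, 0.75, 0.999),
) -> pd.DataFrame:
    """Per-volume (and per-region) intensity summaries for preprocessing QC.

    ``region_masks`` maps region name -> {volume id -> binary mask}.  Each row
    carries min/max/mean, the requested quantiles, and fixed-bin histogram
    counts, mirroring the before/after histogram check used to validate
    normalisation across scanners.
    """
    rows = []
    regions: dict[str, Mapping[str, Volume]] = {"volume": {}}
    if region_masks:
        regions.update(region_masks)
    for vid, vol in volumes.items():
        data = vol.data
        for region_name, masks in regions.items():
            if region_name == "volume":
                values = data.ravel()
            else:
                if vid not in masks:
                    continue
                m = masks[vid].data.astype(bool)
                if m.shape != data.shape:
                    raise ValueError(
                        f"mask for region {region_name!r} of volume {vid!r} has shape "
                        f"{m.shape}, expected {data.shape}"
                    )
                values = data[m]
            if values.size == 0:
                continue
            counts, edges = np.histogram(values, bins=n_bins)
            row = {
                "volume_id": vid,
                "region": region_name,
                "n_voxels": int(values.size),
                "min": float(values.min()),
                "max": float(values.max()),
                "mean": float(values.mean()),
                "hist_counts": counts.tolist(),
                "hist_edges": edges.tolist(),
            }
            for q, v in zip(quantiles, np.quantile(values, quantiles)):
                row[f"q{q:g}"] = float(v)
            rows.append(row)
    return pd.DataFrame(rows)
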