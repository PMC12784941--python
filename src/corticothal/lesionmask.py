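"""Lesion-artifact voxel exclusion and per-ROI validity.

Focal injury produces local signal anomalies (microbleed hypointensity,
CSF/edema hyperintensity) that would corrupt ROI-mean fMRI signals. The
rule implemented here compares globally normalized mean images of each
post-injury scan against baseline: voxels whose absolute intensity change
exceeds ``factor`` times the grand mean baseline intensity (in-mask mean of
the normalized baseline images, averaged across the cohort) are excluded,
and an ROI losing strictly more than ``max_fraction`` of its voxels is
omitted from the connectivity analysis altogether. Excluded voxels in
retained ROIs are dropped from the ROI mean time series.

Volumes are assumed co-registered upstream; no resampling happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .motionfc import ROITimeSeriesSet

logger = logging.getLogger(__name__)

DEFAULT_EXCLUSION_FACTOR = 2.5
DEFAULT_MAX_EXCLUDED_FRACTION = 0.30


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D intensity grid with isotropic-or-not voxel size in mm."""

    data: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {d.shape}")
        object.__setattr__(self, "data", d)

    @property
    def shape(self):
        return self.data.shape


@dataclass(frozen=True)
class ExclusionResult:
    """Voxel exclusion flags plus the per-ROI validity decision."""

    excluded: np.ndarray  # 3-D bool
    excluded_fraction: dict  # roi name -> fraction in [0, 1]
    valid: dict  # roi name -> bool


def mean_volume(series_4d: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> VoxelVolume:
    """Voxel-wise arithmetic mean over all volumes of a 4-D (x, y, z, t) series."""
    s = np.asarray(series_4d, dtype=float)
    if s.ndim != 4 or s.shape[3] < 1:
        raise ValueError(f"expected a 4-D (x, y, z, t) series, got shape {s.shape}")
    return VoxelVolume(s.mean(axis=3), voxel_size_mm)


def global_normalize(vol: VoxelVolume, brain_mask: np.ndarray) -> VoxelVolume:
    """Divide intensities by the in-mask mean so the normalized in-mask mean is 1."""
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    if not mask.any():
        raise ValueError("brain mask is empty")
    m = float(vol.data[mask].mean())
    if m <= 0:
        raise ValueError(f"in-mask mean intensity is {m}; must be positive")
    return VoxelVolume(vol.data / m, vol.voxel_size_mm)


def grand_baseline_mean(normalized_baselines: list, brain_mask: np.ndarray) -> float:
    """In-mask mean of normalized baseline volumes averaged across the cohort.

    After per-scan global normalization each term is 1 by construction; the
    function exists so the threshold's reference is computed, not assumed,
    when normalization conventions change.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not normalized_baselines:
        raise ValueError("no baseline volumes supplied")
    vals = [float(v.data[mask].mean()) for v in normalized_baselines]
    return float(np.mean(vals))


def exclusion_mask(
    post_norm: VoxelVolume,
    base_norm: VoxelVolume,
    grand_baseline_mean: float,
    factor: float = DEFAULT_EXCLUSION_FACTOR,
) -> np.ndarray:
    """Voxels whose absolute normalized change strictly exceeds
    ``factor * grand_baseline_mean``.

    The absolute difference is used: hypo- and hyperintense anomalies are
    both artifacts to remove. The inequality is strict ("exceeding").
    """
    if post_norm.shape != base_norm.shape:
        raise ValueError(
            f"grid mismatch: post {post_norm.shape} vs baseline {base_norm.shape}"
        )
    if grand_baseline_mean <= 0:
        raise ValueError("grand baseline mean must be positive")
    diff = np.abs(post_norm.data - base_norm.data)
    return diff > factor * grand_baseline_mean


def roi_validity(
    excluded: np.ndarray,
    roi_masks: dict,
    max_fraction: float = DEFAULT_MAX_EXCLUDED_FRACTION,
) -> ExclusionResult:
    """Per-ROI excluded-voxel fraction and validity.

    An ROI is omitted when strictly more than ``max_fraction`` of its voxels
    are excluded; exactly at the threshold it is retained.
    """
    excluded = np.asarray(excluded, dtype=bool)
    fractions, valid = {}, {}
    for name, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"ROI {name!r} is empty")
        frac = float((excluded & mask).sum() / n)
        fractions[name] = frac
        valid[name] = frac <= max_fraction
        if not valid[name]:
            logger.info("ROI %s omitted: %.1f%% voxels excluded", name, 100 * frac)
    return ExclusionResult(excluded=excluded, excluded_fraction=fractions, valid=valid)


def roi_mean_timeseries(
    series_4d: np.ndarray,
    roi_masks: dict,
    excluded: np.ndarray | None = None,
    validity: ExclusionResult | None = None,
) -> ROITimeSeriesSet:
    """ROI-mean time series from a 4-D (x, y, z, t) series.

    Excluded voxels are dropped from the mean of retained ROIs; omitted ROIs
    get a NaN series and a False validity flag.
    """
    s = np.asarray(series_4d, dtype=float)
    if s.ndim != 4:
        raise ValueError(f"expected a 4-D series, got shape {s.shape}")
    names = tuple(roi_masks)
    n_t = s.shape[3]
    out = np.full((n_t, len(names)), np.nan)
    valid = np.ones(len(names), dtype=bool)
    for j, name in enumerate(names):
        mask = np.asarray(roi_masks[name], dtype=bool)
        if validity is not None and not validity.valid.get(name, True):
            valid[j] = False
            continue
        if excluded is not None:
            mask = mask & ~np.asarray(excluded, dtype=bool)
        if not mask.any():
            logger.warning("ROI %s has no usable voxels; series set missing", name)
            valid[j] = False
            continue
        out[:, j] = s[mask].mean(axis=0)
    return ROITimeSeriesSet(roi_names=names, series=out, valid=valid)
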