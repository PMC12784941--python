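"""TSPO-PET uptake quantification.

Dynamic frames are summed over a late post-injection interval (default
15-60 min), normalized to the total activity in the rostro-thoracic body
mask, and reported per ROI as a percentage of total uptake per ml (%/ml).
Normalizing to in-field-of-view body uptake makes the measure independent
of injected dose, so global activity rescaling leaves U unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lesionmask import VoxelVolume

logger = logging.getLogger(__name__)

DEFAULT_SUM_START_MIN = 15.0
DEFAULT_SUM_END_MIN = 60.0


@dataclass(frozen=True)
class DynamicPET:
    """Dynamic PET acquisition: activity-concentration frames with timing.

    Attributes
    ----------
    frames : (n_frames, x, y, z) array
        Activity concentration per frame (activity per ml).
    frame_times_min : (n_frames, 2) array
        Start and end of each frame, minutes post-injection; time-ordered
        and non-overlapping.
    voxel_volume_ml : float
    """

    frames: np.ndarray
    frame_times_min: np.ndarray
    voxel_volume_ml: float = 1.0

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=float)
        t = np.asarray(self.frame_times_min, dtype=float)
        if f.ndim != 4:
            raise ValueError(f"frames must be (n_frames, x, y, z), got {f.shape}")
        if t.shape != (f.shape[0], 2):
            raise ValueError(
                f"frame_times_min shape {t.shape} does not match {f.shape[0]} frames"
            )
        if np.any(t[:, 1] <= t[:, 0]):
            raise ValueError("each frame must end after it starts")
        if np.any(t[1:, 0] < t[:-1, 1] - 1e-9):
            raise ValueError("frames must be time-ordered and non-overlapping")
        if np.any(f < 0):
            raise ValueError("activity concentrations must be non-negative")
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "frame_times_min", t)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def sum_frames(
    pet: DynamicPET,
    t_start: float = DEFAULT_SUM_START_MIN,
    t_end: float = DEFAULT_SUM_END_MIN,
) -> VoxelVolume:
    """Duration-weighted sum of frames overlapping ``[t_start, t_end]`` min.

    Each frame contributes its concentration times the duration of its
    overlap with the interval, so a partially covered frame is weighted by
    the overlap only. Equivalent to mean activity times total duration.
    """
    starts, ends = pet.frame_times_min[:, 0], pet.frame_times_min[:, 1]
    overlap = np.minimum(ends, t_end) - np.maximum(starts, t_start)
    overlap = np.clip(overlap, 0.0, None)
    if not np.any(overlap > 0):
        raise ValueError(
            f"no frames overlap the summation interval [{t_start}, {t_end}] min"
        )
    summed = np.tensordot(overlap, pet.frames, axes=(0, 0))
    return VoxelVolume(summed)


def normalize_uptake(
    summed: VoxelVolume | np.ndarray,
    body_mask: np.ndarray,
    voxel_volume_ml: float,
) -> tuple[VoxelVolume, float]:
    """Normalize to total in-mask uptake; returns (U volume in %/ml, total).

    ``U(voxel) = 100 * value(voxel) / sum_mask(value * voxel_volume_ml)``,
    so integrating U over the body mask gives exactly 100 %.
    """
    data = summed.data if isinstance(summed, VoxelVolume) else np.asarray(summed, float)
    mask = np.asarray(body_mask, dtype=bool)
    if mask.shape != data.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {data.shape}")
    if not mask.any():
        raise ValueError("body mask is empty")
    total = float(data[mask].sum() * voxel_volume_ml)
    if total <= 0:
        raise ValueError("total in-mask activity must be positive")
    return VoxelVolume(100.0 * data / total), total


def roi_uptake(u_volume: VoxelVolume, roi_masks: dict) -> pd.DataFrame:
    """Per-ROI mean normalized uptake (%/ml) as a tidy table."""
    rows = []
    for name, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != u_volume.shape:
            raise ValueError(f"ROI {name!r} grid does not match the uptake volume")
        if not mask.any():
            raise ValueError(f"ROI {name!r} is empty")
        rows.append({"roi": name, "u_feppa": float(u_volume.data[mask].mean())})
    return pd.DataFrame(rows)


def injection_qc(
    pet: DynamicPET,
    body_mask: np.ndarray,
    early_window_min: float = 5.0,
    tolerance: float = 0.05,
) -> tuple[bool, np.ndarray]:
    """Flag scans with a faulty tail-vein injection from the time-activity curve.

    A successful bolus produces a monotone rise of the whole-mask activity
    during the first ``early_window_min`` minutes; a drop of more than
    ``tolerance`` times the curve maximum between consecutive early frames
    flags the scan. Returns ``(ok, whole-mask TAC)``.
    """
    mask = np.asarray(body_mask, dtype=bool)
    tac = pet.frames[:, mask].mean(axis=1)
    mid = pet.frame_times_min.mean(axis=1)
    early = tac[mid <= early_window_min]
    if early.size < 2:
        logger.warning("fewer than 2 early frames; injection QC inconclusive")
        return True, tac
    drops = np.diff(early)
    ok = bool(np.all(drops >= -tolerance * tac.max()))
    return ok, tac
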