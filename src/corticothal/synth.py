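"""Synthetic cohort generator with known ground truth.

The generator emulates a longitudinal rat TBI study: two groups (TBI,
SHAM) followed over four timepoints (BL, W2, M2, M6) with six regions of
interest — ipsi/contralateral ventral posterior (VPNi/VPNc) and lateral
(LNi/LNc) thalamic nuclei plus retrosplenial (RS) and cingulate (CG)
cortex. Every modality the analysis pipeline consumes is simulated on a
small digital phantom:

* ROI fMRI time series as correlated Gaussian AR(1) processes whose
  instantaneous cross-correlation equals a per-subject target matrix,
  with group- and timepoint-dependent ipsilateral connectivity deficits;
* rigid-body motion traces (baseline jitter plus step-like spikes);
* mean anatomical volumes with a growing focal hyperintense lesion;
* dynamic PET frames with elevated ipsilateral thalamic tracer uptake;
* diffusion-weighted signals from a voxel-wise tensor field with
  increased ipsilateral thalamic diffusivity;
* detected-nucleus area tables with bimodal (neuronal/glial) sizes,
  ROI areas, and myelin staining intensities.

A per-subject latent inflammation severity couples the ipsilateral PET
elevation to the diffusivity, histology, and (at M2 only) connectivity
lateralization, so the downstream correlation analysis has a known
generating pattern. Observed records never carry ground-truth fields;
truth lives in a separate ``SubjectTruth`` sidecar. All generators are
pure functions of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

from .dtimetrics import DiffusionProtocol
from .lesionmask import VoxelVolume
from .motionfc import MotionTrace, ROITimeSeriesSet, ScanQC
from .petquant import DynamicPET

logger = logging.getLogger(__name__)

GROUP_TBI = "TBI"
GROUP_SHAM = "SHAM"
DEFAULT_TIMEPOINTS = ("BL", "W2", "M2", "M6")
DEFAULT_ROI_NAMES = ("VPNi", "VPNc", "LNi", "LNc", "RS", "CG")
HISTO_TIMEPOINT = "M8"

_THAL = (0, 1, 2, 3)
_IPSI_THAL = (0, 2)
_CORTEX = (4, 5)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# configuration blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotionSpec:
    """Rigid-motion model: per-volume jitter plus sparse step spikes."""

    jitter_mm: float = 0.0075
    spike_rate: float = 0.01
    spike_amplitude_mm: float = 0.15
    spike_amplitude_sd_mm: float = 0.05
    rotation_fraction: float = 0.1  # rotation jitter at 10% of translation scale
    rotation_radius_mm: float = 5.0


@dataclass(frozen=True)
class LesionSpec:
    """Focal hyperintense anomaly growing over post-injury timepoints."""

    center: tuple = (8, 16, 8)
    radius_by_timepoint: dict = field(
        default_factory=lambda: {"BL": 0.0, "W2": 1.4, "M2": 2.4, "M6": 2.6}
    )
    intensity_factor: float = 4.0  # lesion intensity relative to brain mean


@dataclass(frozen=True)
class PETSpec:
    """Dynamic PET: tissue activity concentrations and frame timing."""

    frame_edges_min: tuple = (0, 2, 5, 10, 15, 20, 30, 40, 50, 60, 70)
    body_activity: float = 1.0
    brain_activity: float = 1.2
    cortex_activity: float = 1.5
    thalamus_activity: float = 1.8
    ipsi_coupling: float = 0.5  # ipsi thalamic elevation per unit latent severity
    subject_noise_sd: float = 0.04
    frame_noise_sd: float = 0.05
    total_body_volume_ml: float = 150.0
    n_scanned: tuple = (25, 9)  # (TBI, SHAM) imaged at W2
    n_faulty: tuple = (7, 1)  # faulty tail-vein injections among scanned


@dataclass(frozen=True)
class DTISpec:
    """Tensor field: per-tissue eigenvalues (mm^2/s) and acquisition noise."""

    thalamus_evals: tuple = (1.05e-3, 0.65e-3, 0.55e-3)
    cortex_evals: tuple = (0.95e-3, 0.75e-3, 0.70e-3)
    background_evals: tuple = (1.40e-3, 0.40e-3, 0.30e-3)
    csf_evals: tuple = (2.0e-3, 2.0e-3, 2.0e-3)
    md_coupling: dict = field(default_factory=lambda: {"M2": 0.25, "M6": 0.30})
    # extra radial-eigenvalue scaling per unit latent severity: gliosis and
    # fiber disorganization reduce anisotropy, so ipsilateral FA falls
    fa_coupling: dict = field(default_factory=lambda: {"M2": 0.10, "M6": 0.10})
    subject_noise_sd: float = 0.03
    voxel_noise_sd: float = 0.02
    b_value: float = 2800.0
    n_directions: int = 42
    n_b0: int = 4
    s0: float = 1000.0
    snr: float = 30.0


@dataclass(frozen=True)
class NucleiParams:
    """Per-class nuclear-area distributions (um^2), Gaussian truncated at 0."""

    neuronal_mean: float = 133.5
    neuronal_sd: float = 40.75
    glial_mean: float = 21.0
    glial_sd: float = 6.5


@dataclass(frozen=True)
class HistoSpec:
    nuclei: NucleiParams = field(default_factory=NucleiParams)
    n_training_neuronal: int = 966
    n_training_glial: int = 731
    neuronal_density_contra: float = 650.0  # cells/mm^2
    glial_density_contra: float = 900.0
    neuronal_coupling: float = -0.25  # ipsi change per unit latent severity
    glial_coupling: float = 0.6
    od_contra: float = 0.5
    od_coupling: float = -0.25
    rs_branding_od_factor: float = 0.95  # staining artifact on RSi, both groups
    section_area_mm2: float = 1.5
    area_noise_sd: float = 0.08
    side_noise_sd: float = 0.05
    contaminant_fraction: float = 0.03  # detections outside both class intervals
    i_bg: float = 0.10
    i_wm: float = 1.00
    reference_noise_sd: float = 0.02
    od_noise_sd: float = 0.02
    sections: tuple = (1, 2, 3)
    n_subset: tuple = (14, 6)  # (TBI, SHAM) with histology, among PET-successful


@dataclass(frozen=True)
class FCSpec:
    """Connectivity targets and group/timepoint deficits (Pearson-r units)."""

    thal_thal: float = 0.45
    cortico_thal: float = 0.40
    cortex_cortex: float = 0.60
    edge_noise_sd: float = 0.02  # between-subject edge-wise variability
    w2_bilateral_deficit: float = 0.10
    w2_ipsi_extra_mean: float = 0.03
    w2_ipsi_extra_sd: float = 0.06
    w2_thal_ipsi_deficit: float = 0.10
    w2_thal_ipsi_sd: float = 0.03
    m2_bilateral_deficit: float = 0.03
    m2_ipsi_coupling: float = 0.15  # coupled to latent severity
    m2_ipsi_sd: float = 0.02
    m2_thal_ipsi_deficit: float = 0.05
    m6_ipsi_mean: float = 0.03
    m6_ipsi_sd: float = 0.02
    sham_w2_rs_boost: float = 0.04  # craniotomy-related RS increase in SHAM
    motion_gain: float = 0.2  # leakage of motion regressors into ROI series


@dataclass(frozen=True)
class LatentSpec:
    """Per-subject latent inflammation severity."""

    tbi_mean: float = 1.0
    tbi_sd: float = 0.4
    tbi_min: float = 0.2
    sham_mean: float = 0.05
    sham_sd: float = 0.05
    sham_min: float = 0.0


@dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic study."""

    n_tbi: int = 36
    n_sham: int = 11
    timepoints: tuple = DEFAULT_TIMEPOINTS
    roi_names: tuple = DEFAULT_ROI_NAMES
    n_volumes: int = 1500
    tr_seconds: float = 1.0
    ar_coefficient: float = 0.3
    grid_shape: tuple = (24, 24, 12)
    scan_bad_rate: float = 16 / 188  # chance a scan fails component-removal QC
    volume_noise_sd: float = 0.05
    group_effects: bool = True
    fc_base_override: tuple | None = None  # full ROIxROI matrix (nested tuples)
    seed: int = 0
    motion: MotionSpec = field(default_factory=MotionSpec)
    lesion: LesionSpec = field(default_factory=LesionSpec)
    pet: PETSpec = field(default_factory=PETSpec)
    dti: DTISpec = field(default_factory=DTISpec)
    histo: HistoSpec = field(default_factory=HistoSpec)
    fc: FCSpec = field(default_factory=FCSpec)
    latent: LatentSpec = field(default_factory=LatentSpec)

    def validate(self) -> None:
        if self.n_volumes < 600:
            raise ValueError("n_volumes must be at least 600")
        if not (0.0 <= self.motion.spike_rate <= 1.0):
            raise ValueError("motion spike rate must lie in [0, 1]")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ValueError("ar_coefficient must lie in [0, 1)")
        p = self.histo.nuclei
        if p.neuronal_sd <= 0 or p.glial_sd <= 0:
            raise ValueError("nuclear-area SDs must be positive")
        _check_correlation_target(self.base_fc_matrix(), name="fc_target[base]")
        for group in (GROUP_TBI, GROUP_SHAM):
            for tp in self.timepoints:
                target = self.group_fc_target(group, tp)
                _check_correlation_target(target, name=f"fc_target[{group}, {tp}]")

    def base_fc_matrix(self) -> np.ndarray:
        if self.fc_base_override is not None:
            m = np.asarray(self.fc_base_override, dtype=float)
        else:
            k = len(self.roi_names)
            m = np.eye(k)
            for i, j in combinations(_THAL, 2):
                m[i, j] = m[j, i] = self.fc.thal_thal
            for c in _CORTEX:
                for t in _THAL:
                    m[c, t] = m[t, c] = self.fc.cortico_thal
            m[4, 5] = m[5, 4] = self.fc.cortex_cortex
        return m

    def group_fc_target(self, group: str, timepoint: str) -> np.ndarray:
        """Expected (mean-latent, noise-free) correlation target."""
        latent = self.latent.tbi_mean if group == GROUP_TBI else self.latent.sham_mean
        return _apply_fc_effects(self, group, timepoint, latent, rng=None)


def _check_correlation_target(m: np.ndarray, name: str = "corr_target") -> None:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ValueError(f"{name} does not have a unit diagonal")
    if np.linalg.eigvalsh(m).min() < -1e-8:
        raise ValueError(f"{name} is not positive semidefinite")


def _nearest_unit_diag_psd(m: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone and renormalize the diagonal."""
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    if w.min() < 1e-10:
        m = (v * np.clip(w, 1e-6, None)) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return (m + m.T) / 2.0


def _apply_fc_effects(
    config: SynthConfig,
    group: str,
    timepoint: str,
    latent: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Group/timepoint/latent connectivity target for one subject.

    ``rng=None`` yields the noise-free expectation (used for validation and
    calibration checks).
    """
    spec = config.fc
    m = config.base_fc_matrix()
    if not config.group_effects:
        return _nearest_unit_diag_psd(m)

    def noise(sd):
        return 0.0 if rng is None else rng.normal(0.0, sd)

    ipsi_ct = [(c, t) for c in _CORTEX for t in _IPSI_THAL]
    all_ct = [(c, t) for c in _CORTEX for t in _THAL]
    thal_ipsi = [p for p in combinations(_THAL, 2) if p[0] in _IPSI_THAL or p[1] in _IPSI_THAL]

    def subtract(pairs, amount):
        for i, j in pairs:
            m[i, j] -= amount
            m[j, i] -= amount

    if group == GROUP_TBI:
        if timepoint == "W2":
            subtract(all_ct, spec.w2_bilateral_deficit)
            # small, subject-variable (sign-free) lateral excess: the subacute
            # asymmetry exists on average but is not driven by the latent severity
            subtract(ipsi_ct, spec.w2_ipsi_extra_mean + noise(spec.w2_ipsi_extra_sd))
            subtract(thal_ipsi, max(0.0, spec.w2_thal_ipsi_deficit + noise(spec.w2_thal_ipsi_sd)))
        elif timepoint == "M2":
            subtract(all_ct, spec.m2_bilateral_deficit)
            subtract(ipsi_ct, max(0.0, spec.m2_ipsi_coupling * latent + noise(spec.m2_ipsi_sd)))
            subtract(thal_ipsi, spec.m2_thal_ipsi_deficit)
        elif timepoint == "M6":
            subtract(ipsi_ct, max(0.0, spec.m6_ipsi_mean + noise(spec.m6_ipsi_sd)))
    elif timepoint == "W2":  # SHAM craniotomy effect on retrosplenial edges
        for j in (0, 1, 2, 3, 5):
            m[4, j] += spec.sham_w2_rs_boost
            m[j, 4] += spec.sham_w2_rs_boost

    if rng is not None and spec.edge_noise_sd > 0:
        k = m.shape[0]
        pert = rng.normal(0.0, spec.edge_noise_sd, size=(k, k))
        pert = (pert + pert.T) / 2.0
        np.fill_diagonal(pert, 0.0)
        m = m + pert
    m = np.clip(m, -0.95, 0.95)
    np.fill_diagonal(m, 1.0)
    return _nearest_unit_diag_psd(m)


# ---------------------------------------------------------------------------
# digital phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Phantom:
    """Voxel grid with brain/body masks and box-shaped ROI masks."""

    shape: tuple
    brain_mask: np.ndarray
    body_mask: np.ndarray
    roi_masks: dict
    voxel_volume_ml: float


def build_phantom(
    shape: tuple = (24, 24, 12),
    roi_names: tuple = DEFAULT_ROI_NAMES,
    total_body_volume_ml: float = 150.0,
) -> Phantom:
    """Rectangular phantom with disjoint ROI boxes inside a brain box.

    The ipsilateral (injured) hemisphere is the low-x half.
    """
    body = np.ones(shape, dtype=bool)
    brain = np.zeros(shape, dtype=bool)
    brain[3:21, 3:21, 2:10] = True
    boxes = {
        "VPNi": (slice(5, 9), slice(8, 12), slice(4, 8)),
        "VPNc": (slice(15, 19), slice(8, 12), slice(4, 8)),
        "LNi": (slice(5, 9), slice(13, 17), slice(4, 8)),
        "LNc": (slice(15, 19), slice(13, 17), slice(4, 8)),
        "RS": (slice(10, 14), slice(15, 19), slice(7, 10)),
        "CG": (slice(10, 14), slice(4, 8), slice(7, 10)),
    }
    rois = {}
    for name in roi_names:
        mask = np.zeros(shape, dtype=bool)
        mask[boxes[name]] = True
        rois[name] = mask
    return Phantom(
        shape=tuple(shape),
        brain_mask=brain,
        body_mask=body,
        roi_masks=rois,
        voxel_volume_ml=total_body_volume_ml / float(body.sum()),
    )


def sphere_mask(shape: tuple, center: tuple, radius: float) -> np.ndarray:
    if radius <= 0:
        return np.zeros(shape, dtype=bool)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


# ---------------------------------------------------------------------------
# per-modality generators
# ---------------------------------------------------------------------------


def generate_roi_timeseries(
    corr_target: np.ndarray,
    n_volumes: int,
    ar_coefficient: float,
    seed,
    roi_names: tuple | None = None,
    burn_in: int = 100,
) -> ROITimeSeriesSet:
    """Stationary Gaussian AR(1) series with a target instantaneous correlation.

    Independent unit-variance AR(1) channels (innovations scaled by
    sqrt(1 - phi^2)) are mixed by the symmetric square root of the target
    matrix, so the population cross-correlation equals ``corr_target`` and
    every channel keeps lag-1 autocorrelation ``ar_coefficient``.
    """
    rng = _as_rng(seed)
    target = np.asarray(corr_target, dtype=float)
    _check_correlation_target(target)
    if not (0.0 <= ar_coefficient < 1.0):
        raise ValueError("ar_coefficient must lie in [0, 1)")
    k = target.shape[0]
    w, v = np.linalg.eigh(target)
    mixer = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    innovations = rng.standard_normal((n_volumes + burn_in, k))
    innovations *= np.sqrt(1.0 - ar_coefficient**2)
    x = lfilter([1.0], [1.0, -ar_coefficient], innovations, axis=0)[burn_in:]
    names = tuple(roi_names) if roi_names is not None else tuple(
        f"roi{i}" for i in range(k)
    )
    return ROITimeSeriesSet(roi_names=names, series=x @ mixer.T)


def generate_motion_trace(
    n_volumes: int,
    spike_rate: float,
    spike_amplitude_mm: float,
    seed,
    jitter_mm: float = 0.0075,
    spike_amplitude_sd_mm: float = 0.0,
    rotation_fraction: float = 0.1,
    rotation_radius_mm: float = 5.0,
    spike_indices=None,
):
    """Rigid-motion trace: Gaussian jitter plus step-like position spikes.

    Spikes are persistent translation offsets entering at random volumes
    (never volume 0), so each produces a single framewise-displacement
    excursion. Rotations are jittered at ``rotation_fraction`` of the
    translation scale (expressed through the rotation radius). Returns
    ``(MotionTrace, spike_indices)`` — the indices are ground truth and are
    not part of the observed trace.
    """
    if not (0.0 <= spike_rate <= 1.0):
        raise ValueError("spike_rate must lie in [0, 1]")
    rng = _as_rng(seed)
    translations = rng.normal(0.0, jitter_mm, size=(n_volumes, 3))
    rot_scale = rotation_fraction * jitter_mm / rotation_radius_mm
    rotations = rng.normal(0.0, rot_scale, size=(n_volumes, 3))
    if spike_indices is None:
        hits = rng.random(n_volumes) < spike_rate
        hits[0] = False
        spike_indices = np.flatnonzero(hits)
    else:
        spike_indices = np.asarray(spike_indices, dtype=int)
    for idx in spike_indices:
        amp = abs(rng.normal(spike_amplitude_mm, spike_amplitude_sd_mm))
        axis = rng.integers(3)
        translations[idx:, axis] += rng.choice([-1.0, 1.0]) * amp
    return (
        MotionTrace(translations=translations, rotations=rotations),
        np.asarray(spike_indices, dtype=int),
    )


def _truncated_normal(rng, mean, sd, size, low=0.0):
    """Gaussian draws resampled (truncated) at ``low``; resampling is logged."""
    out = rng.normal(mean, sd, size=size)
    n_resampled = 0
    bad = out <= low
    while bad.any():
        n_resampled += int(bad.sum())
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= low
    if n_resampled:
        logger.debug("resampled %d out-of-range area draws", n_resampled)
    return out


def generate_nuclei(
    n_neuronal: int,
    n_glial: int,
    nuclei_params: NucleiParams,
    seed,
) -> pd.DataFrame:
    """Nucleus-area table with per-class truncated-Gaussian areas.

    Returns a DataFrame with columns ``area_um2`` and ``true_class`` (the
    generating label — strip it before treating the table as observed data).
    """
    if n_neuronal < 0 or n_glial < 0:
        raise ValueError("nucleus counts must be non-negative")
    rng = _as_rng(seed)
    p = nuclei_params
    areas = np.concatenate(
        [
            _truncated_normal(rng, p.neuronal_mean, p.neuronal_sd, n_neuronal),
            _truncated_normal(rng, p.glial_mean, p.glial_sd, n_glial),
        ]
    )
    labels = ["neuronal"] * n_neuronal + ["glial"] * n_glial
    return pd.DataFrame({"area_um2": areas, "true_class": labels})


def generate_training_nuclei(config: SynthConfig, seed):
    """Manually-curated training sample stand-in: per-class area arrays."""
    rng = _as_rng(seed)
    p = config.histo.nuclei
    neuronal = _truncated_normal(rng, p.neuronal_mean, p.neuronal_sd,
                                 config.histo.n_training_neuronal)
    glial = _truncated_normal(rng, p.glial_mean, p.glial_sd,
                              config.histo.n_training_glial)
    return neuronal, glial


def generate_lesion_volume(
    phantom: Phantom,
    radius: float,
    intensity_factor: float,
    seed,
    center: tuple = (8, 16, 8),
    noise_sd: float = 0.05,
):
    """Mean anatomical proxy volume with an optional focal hyperintensity.

    Baseline tissue intensity is 1 inside the brain mask and 0.2 outside;
    lesion voxels take ``intensity_factor`` (in brain-mean units). Returns
    ``(VoxelVolume, lesion_mask)``; the mask is ground truth.
    """
    rng = _as_rng(seed)
    base = np.where(phantom.brain_mask, 1.0, 0.2)
    lesion = sphere_mask(phantom.shape, center, radius) & phantom.brain_mask
    data = np.where(lesion, float(intensity_factor), base)
    data = data * (1.0 + rng.normal(0.0, noise_sd, size=phantom.shape))
    return VoxelVolume(np.clip(data, 0.0, None)), lesion


def _pet_time_course(t_mid: np.ndarray, faulty: bool) -> np.ndarray:
    if faulty:  # paravenous bolus: early peak then washout, no uptake plateau
        return 1.5 * np.exp(-t_mid / 6.0) + 0.25
    rise = np.clip(t_mid / 10.0, 0.0, 1.0)
    return rise * np.exp(-0.004 * np.clip(t_mid - 10.0, 0.0, None))


def generate_pet_frames(
    phantom: Phantom,
    concentration_map: np.ndarray,
    seed,
    frame_edges_min: tuple = PETSpec.frame_edges_min,
    faulty: bool = False,
    noise_sd: float = 0.05,
) -> DynamicPET:
    """Dynamic frames: a spatial concentration map modulated by a global
    time-activity curve (monotone early rise for a good injection)."""
    rng = _as_rng(seed)
    edges = np.asarray(frame_edges_min, dtype=float)
    times = np.column_stack([edges[:-1], edges[1:]])
    t_mid = times.mean(axis=1)
    amp = _pet_time_course(t_mid, faulty)
    frames = concentration_map[None] * amp[:, None, None, None]
    frames = frames * (1.0 + rng.normal(0.0, noise_sd, size=frames.shape))
    return DynamicPET(
        frames=np.clip(frames, 0.0, None),
        frame_times_min=times,
        voxel_volume_ml=phantom.voxel_volume_ml,
    )


def _pet_concentration_map(
    config: SynthConfig, phantom: Phantom, latent: float, rng
) -> np.ndarray:
    spec = config.pet
    conc = np.where(phantom.brain_mask, spec.brain_activity, spec.body_activity)
    for roi in ("RS", "CG"):
        conc[phantom.roi_masks[roi]] = spec.cortex_activity
    for roi in ("VPNc", "LNc"):
        conc[phantom.roi_masks[roi]] = spec.thalamus_activity * (
            1.0 + rng.normal(0.0, spec.subject_noise_sd)
        )
    for roi in ("VPNi", "LNi"):
        conc[phantom.roi_masks[roi]] = spec.thalamus_activity * (
            1.0
            + spec.ipsi_coupling * latent
            + rng.normal(0.0, spec.subject_noise_sd)
        )
    return conc


def uniform_directions(n: int) -> np.ndarray:
    """Deterministic near-uniform unit vectors (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    d = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def default_protocol(
    n_directions: int = 42, n_b0: int = 4, b_value: float = 2800.0
) -> DiffusionProtocol:
    """Single-shell protocol: ``n_b0`` b=0 images plus uniform directions."""
    b = np.concatenate([np.zeros(n_b0), np.full(n_directions, b_value)])
    dirs = np.vstack(
        [np.tile([0.0, 0.0, 1.0], (n_b0, 1)), uniform_directions(n_directions)]
    )
    return DiffusionProtocol(b_values=b, directions=dirs)


def generate_dti_eigenfield(
    phantom: Phantom,
    roi_eigenvalues: dict,
    seed,
    background_evals: tuple = DTISpec.background_evals,
    csf_evals: tuple = DTISpec.csf_evals,
    voxel_noise_sd: float = 0.02,
) -> np.ndarray:
    """Per-voxel descending eigenvalue field (..., 3) on the phantom grid.

    ``roi_eigenvalues`` maps ROI name -> (l1, l2, l3); remaining brain
    voxels take ``background_evals`` and non-brain voxels ``csf_evals``.
    Voxel-wise multiplicative heterogeneity is applied to all three
    eigenvalues jointly so anisotropy is preserved.
    """
    rng = _as_rng(seed)
    evals = np.empty(phantom.shape + (3,))
    evals[...] = np.asarray(csf_evals, dtype=float)
    evals[phantom.brain_mask] = np.asarray(background_evals, dtype=float)
    for roi, lam in roi_eigenvalues.items():
        evals[phantom.roi_masks[roi]] = np.asarray(lam, dtype=float)
    scale = 1.0 + rng.normal(0.0, voxel_noise_sd, size=phantom.shape)
    return evals * np.clip(scale, 0.1, None)[..., None]


def forward_dwi_signals(
    eigenfield: np.ndarray,
    protocol: DiffusionProtocol,
    seed,
    s0: float = 1000.0,
    snr: float | None = 30.0,
) -> np.ndarray:
    """Diffusion-weighted signals from a tensor field with random voxel
    orientations and Rician-like noise (``snr=None`` for noise-free)."""
    rng = _as_rng(seed)
    shape = eigenfield.shape[:-1]
    lam = eigenfield.reshape(-1, 3)
    n_vox = lam.shape[0]
    rot = Rotation.random(n_vox, rng=rng).as_matrix()
    tensors = np.einsum("nij,nj,nkj->nik", rot, lam, rot)
    g = protocol.directions
    quad = np.einsum("mi,nij,mj->nm", g, tensors, g)
    signals = s0 * np.exp(-protocol.b_values[None, :] * quad)
    if snr is not None:
        sigma = s0 / snr
        noise_r = rng.normal(0.0, sigma, size=signals.shape)
        noise_i = rng.normal(0.0, sigma, size=signals.shape)
        signals = np.sqrt((signals + noise_r) ** 2 + noise_i**2)
    return signals.reshape(shape + (protocol.n_measurements,))


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanRecord:
    """One fMRI session: ROI series, motion, QC, and the mean anatomical proxy."""

    timeseries: ROITimeSeriesSet
    motion: MotionTrace
    qc: ScanQC
    mean_volume: VoxelVolume


@dataclass(frozen=True)
class DWIRecord:
    """One diffusion acquisition: signals (..., n_measurements) and protocol."""

    signals: np.ndarray
    protocol: DiffusionProtocol
    s0: float


@dataclass(frozen=True)
class HistologySet:
    """Observed histology for one animal (no ground-truth columns)."""

    nuclei: pd.DataFrame  # section, roi, area_um2
    roi_areas: pd.DataFrame  # section, roi, roi_area_um2
    od: pd.DataFrame  # section, roi, i_roi, i_bg, i_wm


@dataclass(frozen=True)
class SubjectTruth:
    """Generating (latent) values for one subject, kept apart from observations."""

    latent: float
    fc_targets: dict  # timepoint -> correlation matrix actually used
    motion_spikes: dict  # timepoint -> spike indices
    lesion_masks: dict  # timepoint -> bool grid
    pet_scanned: bool
    pet_faulty: bool
    dti_roi_scale: dict  # timepoint -> {roi: eigenvalue scale}
    histo_latents: dict | None  # roi -> dict(cd_ne, cd_gl, od)
    nuclei_true_class: pd.Series | None


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    scans: dict  # timepoint -> ScanRecord
    pet: DynamicPET | None
    dwi: dict  # timepoint -> DWIRecord
    histology: HistologySet | None
    truth: SubjectTruth


@dataclass(frozen=True)
class Cohort:
    subjects: tuple
    config: SynthConfig
    phantom: Phantom

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def by_group(self, group: str):
        return [s for s in self.subjects if s.group == group]


def _draw_latent(config: SynthConfig, group: str, rng) -> float:
    ls = config.latent
    if group == GROUP_TBI:
        return float(max(ls.tbi_min, rng.normal(ls.tbi_mean, ls.tbi_sd)))
    return float(max(ls.sham_min, rng.normal(ls.sham_mean, ls.sham_sd)))


def _scan_qc(config: SynthConfig, rng) -> ScanQC:
    if rng.random() < config.scan_bad_rate:
        n_removed = int(rng.integers(21, 29))
    else:
        n_removed = int(np.clip(rng.binomial(30, 0.33), 0, 20))
    return ScanQC(n_removed=n_removed)


def _dti_roi_scales(config: SynthConfig, timepoint: str, latent: float, rng) -> dict:
    """Per-ROI (overall, extra-radial) eigenvalue scale factors."""
    spec = config.dti
    effects = config.group_effects
    c_md = spec.md_coupling.get(timepoint, 0.0) if effects else 0.0
    c_fa = spec.fa_coupling.get(timepoint, 0.0) if effects else 0.0
    scales = {}
    for roi in ("VPNi", "LNi"):
        overall = max(0.3, 1.0 + c_md * latent + rng.normal(0.0, spec.subject_noise_sd))
        radial = max(0.3, 1.0 + c_fa * latent)
        scales[roi] = (overall, radial)
    for roi in ("VPNc", "LNc", "RS", "CG"):
        overall = max(0.3, 1.0 + rng.normal(0.0, spec.subject_noise_sd))
        scales[roi] = (overall, 1.0)
    return scales


def _subject_histology(config: SynthConfig, latent: float, rng):
    """Observed nucleus/area/OD tables plus the ground-truth sidecar pieces."""
    spec = config.histo
    p = spec.nuclei
    rois = ("VPNi", "VPNc", "LNi", "LNc", "RSi", "RSc")
    ipsi = {"VPNi", "LNi", "RSi"}
    latents = {}
    nuc_rows, area_rows, od_rows = [], [], []
    for roi in rois:
        thalamic = roi.startswith(("VPN", "LN"))
        ne_coupling = spec.neuronal_coupling if (thalamic and roi in ipsi) else 0.0
        gl_coupling = spec.glial_coupling if (thalamic and roi in ipsi) else 0.0
        cd_ne = spec.neuronal_density_contra * max(
            0.05, 1.0 + ne_coupling * latent + rng.normal(0.0, spec.side_noise_sd)
        )
        cd_gl = spec.glial_density_contra * max(
            0.05, 1.0 + gl_coupling * latent + rng.normal(0.0, spec.side_noise_sd)
        )
        od = spec.od_contra * max(
            0.02,
            1.0
            + (spec.od_coupling * latent if (thalamic and roi in ipsi) else 0.0)
            + rng.normal(0.0, spec.side_noise_sd),
        )
        if roi == "RSi":  # branding-mark staining artifact, both groups
            od *= spec.rs_branding_od_factor
        latents[roi] = {"cd_ne": cd_ne, "cd_gl": cd_gl, "od": od}
        for section in spec.sections:
            area_mm2 = spec.section_area_mm2 * max(
                0.2, 1.0 + rng.normal(0.0, spec.area_noise_sd)
            )
            n_ne = rng.poisson(cd_ne * area_mm2)
            n_gl = rng.poisson(cd_gl * area_mm2)
            n_other = rng.poisson(spec.contaminant_fraction * (n_ne + n_gl))
            areas = np.concatenate(
                [
                    _truncated_normal(rng, p.neuronal_mean, p.neuronal_sd, n_ne),
                    _truncated_normal(rng, p.glial_mean, p.glial_sd, n_gl),
                    rng.uniform(p.glial_mean + 3 * p.glial_sd,
                                p.neuronal_mean - 2.2 * p.neuronal_sd, n_other),
                ]
            )
            classes = (
                ["neuronal"] * n_ne + ["glial"] * n_gl + ["other"] * n_other
            )
            nuc_rows.append(
                pd.DataFrame(
                    {
                        "section": section,
                        "roi": roi,
                        "area_um2": areas,
                        "_true_class": classes,
                    }
                )
            )
            area_rows.append(
                {"section": section, "roi": roi, "roi_area_um2": area_mm2 * 1e6}
            )
            i_bg = spec.i_bg * (1.0 + rng.normal(0.0, spec.reference_noise_sd))
            i_wm = spec.i_wm * (1.0 + rng.normal(0.0, spec.reference_noise_sd))
            od_section = od + rng.normal(0.0, spec.od_noise_sd)
            od_rows.append(
                {
                    "section": section,
                    "roi": roi,
                    "i_roi": i_bg + od_section * i_wm,
                    "i_bg": i_bg,
                    "i_wm": i_wm,
                }
            )
    nuclei = pd.concat(nuc_rows, ignore_index=True)
    true_class = nuclei.pop("_true_class")
    histology = HistologySet(
        nuclei=nuclei,
        roi_areas=pd.DataFrame(area_rows),
        od=pd.DataFrame(od_rows),
    )
    return histology, latents, true_class


def _generate_subject(
    config: SynthConfig,
    phantom: Phantom,
    subject_id: str,
    group: str,
    pet_scanned: bool,
    pet_faulty: bool,
    with_histology: bool,
    rng: np.random.Generator,
) -> SubjectRecord:
    latent = _draw_latent(config, group, rng)
    mspec = config.motion
    scans, fc_targets, spikes, lesions = {}, {}, {}, {}
    for tp in config.timepoints:
        target = _apply_fc_effects(config, group, tp, latent, rng)
        ts = generate_roi_timeseries(
            target, config.n_volumes, config.ar_coefficient, rng,
            roi_names=config.roi_names,
        )
        motion, spike_idx = generate_motion_trace(
            config.n_volumes,
            mspec.spike_rate,
            mspec.spike_amplitude_mm,
            rng,
            jitter_mm=mspec.jitter_mm,
            spike_amplitude_sd_mm=mspec.spike_amplitude_sd_mm,
            rotation_fraction=mspec.rotation_fraction,
            rotation_radius_mm=mspec.rotation_radius_mm,
        )
        if config.fc.motion_gain > 0 and mspec.jitter_mm > 0:
            params = motion.parameters
            std = params.std(axis=0)
            std[std == 0] = 1.0
            zparams = (params - params.mean(axis=0)) / std
            mixing = rng.normal(0.0, 1.0 / np.sqrt(6.0), size=(6, ts.n_rois))
            ts = ROITimeSeriesSet(
                roi_names=ts.roi_names,
                series=ts.series + config.fc.motion_gain * (zparams @ mixing),
            )
        radius = (
            config.lesion.radius_by_timepoint.get(tp, 0.0)
            if group == GROUP_TBI
            else 0.0
        )
        volume, lesion = generate_lesion_volume(
            phantom,
            radius,
            config.lesion.intensity_factor,
            rng,
            center=config.lesion.center,
            noise_sd=config.volume_noise_sd,
        )
        scans[tp] = ScanRecord(
            timeseries=ts, motion=motion, qc=_scan_qc(config, rng), mean_volume=volume
        )
        fc_targets[tp] = target
        spikes[tp] = spike_idx
        lesions[tp] = lesion

    pet = None
    if pet_scanned:
        conc = _pet_concentration_map(config, phantom, latent, rng)
        pet = generate_pet_frames(
            phantom,
            conc,
            rng,
            frame_edges_min=config.pet.frame_edges_min,
            faulty=pet_faulty,
            noise_sd=config.pet.frame_noise_sd,
        )

    protocol = default_protocol(
        config.dti.n_directions, config.dti.n_b0, config.dti.b_value
    )
    dwi, dti_scales = {}, {}
    base_thal = np.asarray(config.dti.thalamus_evals)
    base_cortex = np.asarray(config.dti.cortex_evals)
    for tp in ("M2", "M6"):
        if tp not in config.timepoints:
            continue
        scales = _dti_roi_scales(config, tp, latent, rng)
        roi_evals = {}
        for roi in config.roi_names:
            base = base_thal if roi.startswith(("VPN", "LN")) else base_cortex
            overall, radial = scales[roi]
            roi_evals[roi] = base * overall * np.array([1.0, radial, radial])
        field_ = generate_dti_eigenfield(
            phantom,
            roi_evals,
            rng,
            background_evals=config.dti.background_evals,
            csf_evals=config.dti.csf_evals,
            voxel_noise_sd=config.dti.voxel_noise_sd,
        )
        signals = forward_dwi_signals(
            field_, protocol, rng, s0=config.dti.s0, snr=config.dti.snr
        )
        dwi[tp] = DWIRecord(
            signals=signals.astype(np.float32), protocol=protocol, s0=config.dti.s0
        )
        dti_scales[tp] = scales

    histology, histo_latents, true_class = (None, None, None)
    if with_histology:
        histology, histo_latents, true_class = _subject_histology(config, latent, rng)

    truth = SubjectTruth(
        latent=latent,
        fc_targets=fc_targets,
        motion_spikes=spikes,
        lesion_masks=lesions,
        pet_scanned=pet_scanned,
        pet_faulty=pet_faulty,
        dti_roi_scale=dti_scales,
        histo_latents=histo_latents,
        nuclei_true_class=true_class,
    )
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        scans=scans,
        pet=pet,
        dwi=dwi,
        histology=histology,
        truth=truth,
    )


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate the full synthetic cohort (deterministic given ``config.seed``).

    PET is acquired at W2 for the first ``pet.n_scanned`` subjects per
    group, of which the first ``pet.n_faulty`` receive a faulty injection;
    histology is available for the first ``histo.n_subset`` of the
    PET-successful subjects per group, mirroring how longitudinal attrition
    nests the modality subsets.
    """
    config.validate()
    phantom = build_phantom(
        config.grid_shape, config.roi_names, config.pet.total_body_volume_ml
    )
    streams = np.random.SeedSequence(config.seed).spawn(config.n_tbi + config.n_sham)
    subjects = []
    counters = {GROUP_TBI: 0, GROUP_SHAM: 0}
    plan = [(GROUP_TBI, i) for i in range(config.n_tbi)] + [
        (GROUP_SHAM, i) for i in range(config.n_sham)
    ]
    for stream, (group, idx) in zip(streams, plan):
        gi = 0 if group == GROUP_TBI else 1
        n_scanned = config.pet.n_scanned[gi]
        n_faulty = config.pet.n_faulty[gi]
        n_histo = config.histo.n_subset[gi]
        scanned = idx < n_scanned
        faulty = scanned and idx < n_faulty
        # histology subset: first n_histo of the PET-successful subjects
        successful_rank = idx - n_faulty
        with_histo = scanned and not faulty and 0 <= successful_rank < n_histo
        counters[group] += 1
        subjects.append(
            _generate_subject(
                config,
                phantom,
                subject_id=f"{group}{counters[group]:02d}",
                group=group,
                pet_scanned=scanned,
                pet_faulty=faulty,
                with_histology=with_histo,
                rng=np.random.default_rng(stream),
            )
        )
    return Cohort(subjects=tuple(subjects), config=config, phantom=phantom)


def expected_coupling_pattern(config: SynthConfig) -> dict:
    """Which correlation-grid cells the generator couples to the latent
    severity: (nucleus, metric, timepoint) -> bool."""
    cells = {}
    for nucleus in ("LN", "VPN"):
        for tp in ("M2", "M6"):
            for metric in ("MD", "AD", "RD", "FA"):
                cells[(nucleus, metric, tp)] = True
        for metric in ("CD_ne", "CD_gl", "OD"):
            cells[(nucleus, metric, HISTO_TIMEPOINT)] = True
        for tp in ("W2", "M2", "M6"):
            coupled = tp == "M2"
            cells[(nucleus, "FC_CG", tp)] = coupled
            cells[(nucleus, "FC_RS", tp)] = coupled
    return cells
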