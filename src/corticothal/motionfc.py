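"""Head-motion metrics, least-motion segment selection, and ROI connectivity.

The resting-state pipeline implemented here works on per-scan rigid-body
motion parameters and ROI-mean time series:

1. framewise displacement (FD) is computed from the six rigid parameters,
2. the contiguous low-motion window of fixed length (default 300 volumes,
   i.e. 5 min at TR = 1 s) is selected after discarding the initial
   anesthesia-tainted segment,
3. scans in which the upstream component-based cleanup removed more than a
   configurable number of components are discarded entirely,
4. motion parameters are regressed from the windowed series, and
5. pairwise Pearson correlations with their Fisher-z transform form the
   functional-connectivity (FC) matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Default sphere radius (mm) converting rotations to arc displacement.
#: Chosen at rat-brain scale.
DEFAULT_ROTATION_RADIUS_MM = 5.0
DEFAULT_WINDOW_LENGTH = 300
DEFAULT_EXCLUDE_FIRST = 300
DEFAULT_N_COMPONENTS = 30
DEFAULT_MAX_REMOVED = 20

#: Correlations are clipped to this magnitude before atanh so z stays finite.
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class MotionTrace:
    """Per-volume rigid-body motion parameters for one scan.

    Attributes
    ----------
    translations : (n, 3) array, mm
    rotations : (n, 3) array, radians
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.translations, dtype=float)
        r = np.asarray(self.rotations, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3 or r.shape != t.shape:
            raise ValueError(
                f"expected matching (n, 3) translation/rotation arrays, "
                f"got {t.shape} and {r.shape}"
            )
        object.__setattr__(self, "translations", t)
        object.__setattr__(self, "rotations", r)

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    @property
    def parameters(self) -> np.ndarray:
        """(n, 6) array: three translations followed by three rotations."""
        return np.hstack([self.translations, self.rotations])


@dataclass(frozen=True)
class FDTrace:
    """Framewise displacement per volume (mm); the first volume is 0."""

    fd: np.ndarray
    rotation_radius_mm: float = DEFAULT_ROTATION_RADIUS_MM

    @property
    def n_volumes(self) -> int:
        return self.fd.shape[0]

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.fd))

    @property
    def max_fd(self) -> float:
        return float(np.max(self.fd))


@dataclass(frozen=True)
class WindowSelection:
    """A selected contiguous volume window, half-open ``[start, start+length)``."""

    start: int
    length: int
    criterion_value: float

    @property
    def stop(self) -> int:
        return self.start + self.length

    @property
    def slice(self) -> slice:
        return slice(self.start, self.stop)


@dataclass(frozen=True)
class ScanQC:
    """Component-removal bookkeeping for one scan."""

    n_removed: int
    n_components: int = DEFAULT_N_COMPONENTS
    discarded: bool = False

    def __post_init__(self):
        if not (0 <= self.n_removed <= self.n_components):
            raise ValueError(
                f"n_removed={self.n_removed} outside [0, {self.n_components}]"
            )


@dataclass(frozen=True)
class ROITimeSeriesSet:
    """Per-ROI mean signal time series for one scan.

    ``valid`` flags ROIs retained by the lesion-exclusion step; series of
    invalid ROIs are never used downstream.
    """

    roi_names: tuple
    series: np.ndarray  # (n_volumes, n_rois)
    valid: np.ndarray = None  # (n_rois,) bool

    def __post_init__(self):
        names = tuple(self.roi_names)
        s = np.asarray(self.series, dtype=float)
        if s.ndim != 2 or s.shape[1] != len(names):
            raise ValueError(
                f"series shape {s.shape} does not match {len(names)} ROIs"
            )
        v = self.valid
        v = np.ones(len(names), dtype=bool) if v is None else np.asarray(v, bool)
        if v.shape != (len(names),):
            raise ValueError("valid flags must have one entry per ROI")
        object.__setattr__(self, "roi_names", names)
        object.__setattr__(self, "series", s)
        object.__setattr__(self, "valid", v)

    @property
    def n_volumes(self) -> int:
        return self.series.shape[0]

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)


@dataclass(frozen=True)
class FCMatrix:
    """ROI x ROI Pearson (r) and Fisher-z (z) connectivity for one scan.

    Entries involving invalid or degenerate ROIs are NaN (missing), never 0.
    """

    roi_names: tuple
    r: np.ndarray
    z: np.ndarray
    n_samples: int

    def pair(self, roi_a: str, roi_b: str, scale: str = "z") -> float:
        i = self.roi_names.index(roi_a)
        j = self.roi_names.index(roi_b)
        return float((self.z if scale == "z" else self.r)[i, j])


def fisher_z(r):
    """Variance-stabilizing atanh transform with |r| clipped to keep z finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def framewise_displacement(
    motion: MotionTrace, rotation_radius_mm: float = DEFAULT_ROTATION_RADIUS_MM
) -> FDTrace:
    """Framewise displacement from rigid-body parameters.

    FD[t] = sum |dTranslation| + radius * sum |dRotation|, i.e. the sum of
    absolute backward differences of the three translations plus the three
    rotations converted to arc length on a sphere of ``rotation_radius_mm``.
    FD[0] is defined as 0.
    """
    params = motion.parameters
    if params.shape[0] < 2:
        raise ValueError("at least 2 volumes are required for framewise displacement")
    finite = np.isfinite(params).all(axis=1)
    if not finite.all():
        bad = int(np.flatnonzero(~finite)[0])
        raise ValueError(f"non-finite motion parameters at volume {bad}")
    diffs = np.abs(np.diff(params, axis=0))
    fd = np.zeros(params.shape[0])
    fd[1:] = diffs[:, :3].sum(axis=1) + rotation_radius_mm * diffs[:, 3:].sum(axis=1)
    return FDTrace(fd=fd, rotation_radius_mm=rotation_radius_mm)


def select_least_motion_window(
    fd: FDTrace | np.ndarray,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    exclude_first: int = DEFAULT_EXCLUDE_FIRST,
) -> WindowSelection:
    """Select the contiguous window minimizing mean FD.

    Windows start at or after ``exclude_first`` (the initial segment is
    dropped to avoid lingering induction-anesthesia effects). Ties are broken
    by the earliest admissible start.
    """
    values = fd.fd if isinstance(fd, FDTrace) else np.asarray(fd, dtype=float)
    n = values.shape[0]
    required = exclude_first + window_length
    if n < required:
        raise ValueError(
            f"scan has {n} volumes; at least {required} required "
            f"(exclude_first={exclude_first} + window_length={window_length})"
        )
    windows = np.lib.stride_tricks.sliding_window_view(
        values[exclude_first:], window_length
    )
    means = windows.mean(axis=1)
    i = int(np.argmin(means))  # argmin returns the first minimum: earliest tie
    return WindowSelection(
        start=exclude_first + i,
        length=window_length,
        criterion_value=float(means[i]),
    )


def apply_scan_discard_rule(qc: ScanQC, max_removed: int = DEFAULT_MAX_REMOVED) -> ScanQC:
    """Flag a scan for complete discard when strictly more than ``max_removed``
    of its components were removed by the upstream cleanup."""
    return replace(qc, discarded=qc.n_removed > max_removed)


def regress_motion(
    series: np.ndarray | ROITimeSeriesSet,
    motion: MotionTrace,
    window: WindowSelection | None = None,
) -> np.ndarray:
    """OLS-regress intercept + six motion parameters out of each series.

    Regression is performed within ``window`` (the analyzed segment) when one
    is given. Collinear (constant or duplicated) motion columns are dropped
    with a warning; residuals are orthogonal to the retained regressors.

    Returns the residual series as an (n_window, n_series) array.
    """
    y = series.series if isinstance(series, ROITimeSeriesSet) else np.asarray(series, float)
    if y.ndim == 1:
        y = y[:, None]
    params = motion.parameters
    if window is not None:
        y = y[window.slice]
        params = params[window.slice]
    if y.shape[0] != params.shape[0]:
        raise ValueError(
            f"series length {y.shape[0]} does not match motion length {params.shape[0]}"
        )
    # Columns with no variance carry no information beyond the intercept.
    keep = params.std(axis=0) > 1e-12
    if not keep.all():
        logger.warning(
            "dropping %d constant motion regressor(s)", int((~keep).sum())
        )
    x = np.column_stack([np.ones(y.shape[0]), params[:, keep]])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def roi_connectivity(
    series: np.ndarray | ROITimeSeriesSet,
    window: WindowSelection | None = None,
    roi_names: tuple | None = None,
    valid: np.ndarray | None = None,
) -> FCMatrix:
    """Pairwise Pearson correlation of ROI series with Fisher-z transform.

    ``series`` is typically the motion-regressed segment. Zero-variance and
    invalid ROIs get NaN rows/columns (missing, not zero). The diagonal of
    ``r`` is 1 for usable ROIs; ``z`` applies the clipping rule everywhere,
    so its diagonal equals atanh(1 - 1e-7).
    """
    if isinstance(series, ROITimeSeriesSet):
        roi_names = series.roi_names if roi_names is None else tuple(roi_names)
        valid = series.valid if valid is None else np.asarray(valid, bool)
        y = series.series
    else:
        y = np.asarray(series, dtype=float)
        roi_names = tuple(roi_names) if roi_names is not None else tuple(
            f"roi{i}" for i in range(y.shape[1])
        )
    if window is not None:
        y = y[window.slice]
    n, k = y.shape
    if n < 3:
        raise ValueError("at least 3 samples are required for correlation")
    if valid is None:
        valid = np.ones(k, dtype=bool)
    usable = valid.copy()
    stds = y.std(axis=0)
    degenerate = stds <= 0
    if degenerate[usable].any():
        for idx in np.flatnonzero(degenerate & usable):
            logger.warning("ROI %s has zero variance; entries set missing",
                           roi_names[idx])
    usable &= ~degenerate
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable ROIs with non-degenerate series")
    r = np.full((k, k), np.nan)
    sub = np.clip(np.corrcoef(y[:, usable], rowvar=False), -1.0, 1.0)
    np.fill_diagonal(sub, 1.0)
    r[np.ix_(usable, usable)] = sub
    z = np.where(np.isnan(r), np.nan, fisher_z(np.nan_to_num(r)))
    return FCMatrix(roi_names=roi_names, r=r, z=z, n_samples=n)


def connectivity_pipeline(
    series: ROITimeSeriesSet,
    motion: MotionTrace,
    qc: ScanQC | None = None,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    exclude_first: int = DEFAULT_EXCLUDE_FIRST,
    rotation_radius_mm: float = DEFAULT_ROTATION_RADIUS_MM,
    max_removed: int = DEFAULT_MAX_REMOVED,
):
    """Run the per-scan chain: FD -> window -> discard rule -> regression -> FC.

    Returns ``(fd, window, qc, fc)``; ``fc`` is None for a discarded scan.
    """
    fd = framewise_displacement(motion, rotation_radius_mm=rotation_radius_mm)
    window = select_least_motion_window(
        fd, window_length=window_length, exclude_first=exclude_first
    )
    if qc is not None:
        qc = apply_scan_discard_rule(qc, max_removed=max_removed)
        if qc.discarded:
            return fd, window, qc, None
    residuals = regress_motion(series, motion, window)
    fc = roi_connectivity(
        residuals, roi_names=series.roi_names, valid=series.valid
    )
    return fd, window, qc, fc
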