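"""Histological quantification: nuclear-size classification, cell density,
and corrected optical density.

Nissl-detected nuclei are classified as neuronal or glial by nuclear area
using per-class intervals ``mean +/- k*SD`` derived from a manually curated
training sample (k = 2 by default). Cell density is the class count divided
by ROI area (reported per mm^2); myelin staining intensity is corrected as
``OD = (I_ROI - I_BG) / I_WM`` with background and white-matter references
from the same section. Metrics are averaged over the three analysed
sections per animal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SD_MULTIPLIER = 2.0
UM2_PER_MM2 = 1e6

NEURONAL = "neuronal"
GLIAL = "glial"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassThresholds:
    """Closed nuclear-area intervals (um^2) per class, with the generating
    mean/SD retained for the overlap tie-break."""

    neuronal: tuple  # (low, high)
    glial: tuple
    k: float = DEFAULT_SD_MULTIPLIER

    def __post_init__(self):
        for name, (lo, hi) in (("neuronal", self.neuronal), ("glial", self.glial)):
            if lo > hi:
                raise ValueError(f"{name} interval [{lo}, {hi}] has low > high")
            if lo == hi:
                logger.warning("%s interval is degenerate at %s", name, lo)

    def class_mean_sd(self, cls: str) -> tuple:
        """Reconstruct (mean, SD) from the interval and multiplier k."""
        lo, hi = self.neuronal if cls == NEURONAL else self.glial
        mean = (lo + hi) / 2.0
        sd = (hi - lo) / (2.0 * self.k) if self.k > 0 else 0.0
        return mean, sd


def derive_class_thresholds(
    neuronal_areas, glial_areas, k: float = DEFAULT_SD_MULTIPLIER
) -> ClassThresholds:
    """Per-class intervals ``[mean - k*SD, mean + k*SD]`` from training nuclei.

    SD is the sample standard deviation (n - 1 denominator). At least two
    training nuclei per class are required.
    """
    intervals = {}
    for name, areas in ((NEURONAL, neuronal_areas), (GLIAL, glial_areas)):
        a = np.asarray(areas, dtype=float)
        if a.size < 2:
            raise ValueError(f"need at least 2 {name} training nuclei, got {a.size}")
        m, sd = float(a.mean()), float(a.std(ddof=1))
        intervals[name] = (m - k * sd, m + k * sd)
    return ClassThresholds(neuronal=intervals[NEURONAL], glial=intervals[GLIAL], k=k)


def classify_nuclei(table: pd.DataFrame, thresholds: ClassThresholds) -> pd.DataFrame:
    """Assign each nucleus a class from its area (column ``area_um2``).

    Membership is closed on both interval ends. Areas in neither interval
    are ``unclassified`` and excluded from both density counts. Should the
    intervals overlap, ties go to the class with the smaller standardized
    distance |area - class mean| / class SD.
    """
    area = table["area_um2"].to_numpy(dtype=float)
    n_lo, n_hi = thresholds.neuronal
    g_lo, g_hi = thresholds.glial
    in_ne = (area >= n_lo) & (area <= n_hi)
    in_gl = (area >= g_lo) & (area <= g_hi)
    labels = np.full(area.shape, UNCLASSIFIED, dtype=object)
    labels[in_ne & ~in_gl] = NEURONAL
    labels[in_gl & ~in_ne] = GLIAL
    both = in_ne & in_gl
    if both.any():
        nm, nsd = thresholds.class_mean_sd(NEURONAL)
        gm, gsd = thresholds.class_mean_sd(GLIAL)
        nsd = nsd if nsd > 0 else np.finfo(float).eps
        gsd = gsd if gsd > 0 else np.finfo(float).eps
        d_ne = np.abs(area - nm) / nsd
        d_gl = np.abs(area - gm) / gsd
        labels[both] = np.where(d_ne[both] <= d_gl[both], NEURONAL, GLIAL)
    out = table.copy()
    out["cell_class"] = labels
    return out


def cell_density(count: int, roi_area: float, area_units: str = "um2") -> float:
    """Cell density CD = count / ROI area, reported in cells per mm^2."""
    if roi_area <= 0:
        raise ValueError("ROI area must be positive")
    if count < 0:
        raise ValueError("cell count must be non-negative")
    if area_units == "um2":
        roi_area = roi_area / UM2_PER_MM2
    elif area_units != "mm2":
        raise ValueError(f"unknown area units {area_units!r}")
    return count / roi_area


def corrected_od(i_roi: float, i_bg: float, i_wm: float) -> float:
    """Staining-corrected optical density ``(I_ROI - I_BG) / I_WM``.

    May be negative when the ROI is lighter than the background reference;
    such values are flagged in the log but returned as computed.
    """
    if i_wm <= 0:
        raise ValueError("white-matter reference intensity must be positive")
    od = (i_roi - i_bg) / i_wm
    if od < 0:
        logger.warning("negative corrected OD (%.4g): ROI lighter than background", od)
    return od


def section_average(values) -> float:
    """Arithmetic mean across analysed sections (three expected).

    Missing sections are simply omitted; a deviation from three values is
    logged so partial animals remain visible in the audit trail.
    """
    a = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if a.size == 0:
        raise ValueError("no section values to average")
    if a.size != 3:
        logger.warning("averaging %d section value(s); 3 expected", a.size)
    return float(a.mean())


def density_table(
    classified: pd.DataFrame, roi_areas: pd.DataFrame
) -> pd.DataFrame:
    """Per-(roi, section) neuronal/glial densities plus the section average.

    Parameters
    ----------
    classified : DataFrame with columns section, roi, area_um2, cell_class
    roi_areas : DataFrame with columns section, roi, roi_area_um2

    Returns a tidy table with columns roi, section ("mean" for the
    cross-section average), cd_ne, cd_gl (cells/mm^2).
    """
    counts = (
        classified[classified["cell_class"] != UNCLASSIFIED]
        .groupby(["roi", "section", "cell_class"])
        .size()
        .unstack("cell_class", fill_value=0)
    )
    rows = []
    for _, row in roi_areas.iterrows():
        key = (row["roi"], row["section"])
        n_ne = int(counts[NEURONAL].get(key, 0)) if NEURONAL in counts else 0
        n_gl = int(counts[GLIAL].get(key, 0)) if GLIAL in counts else 0
        rows.append(
            {
                "roi": row["roi"],
                "section": row["section"],
                "cd_ne": cell_density(n_ne, row["roi_area_um2"], "um2"),
                "cd_gl": cell_density(n_gl, row["roi_area_um2"], "um2"),
            }
        )
    per_section = pd.DataFrame(rows)
    means = (
        per_section.groupby("roi")[["cd_ne", "cd_gl"]]
        .agg(lambda v: section_average(v.to_numpy()))
        .reset_index()
    )
    means["section"] = "mean"
    return pd.concat([per_section, means], ignore_index=True)


def od_table(od_measurements: pd.DataFrame) -> pd.DataFrame:
    """Corrected OD per (roi, section) and its section average.

    Input columns: section, roi, i_roi, i_bg, i_wm (references taken from
    the same section as the ROI intensity).
    """
    df = od_measurements.copy()
    df["od"] = [
        corrected_od(r.i_roi, r.i_bg, r.i_wm) for r in df.itertuples()
    ]
    means = (
        df.groupby("roi")["od"]
        .agg(lambda v: section_average(v.to_numpy()))
        .reset_index()
    )
    means["section"] = "mean"
    return pd.concat(
        [df[["roi", "section", "od"]], means[["roi", "section", "od"]]],
        ignore_index=True,
    )
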