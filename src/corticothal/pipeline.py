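"""End-to-end orchestration: synthetic cohort -> per-modality tables ->
lateralization deltas -> uptake-asymmetry correlation grid.

Each stage delegates to the corresponding quantification module; this
module only routes data and keeps the tidy-table schemas in one place.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import dtimetrics, histoquant, latstats, lesionmask, motionfc, petquant
from .synth import (
    Cohort,
    SynthConfig,
    generate_cohort,
    generate_training_nuclei,
    HISTO_TIMEPOINT,
)

logger = logging.getLogger(__name__)

NUCLEUS_SIDES = {
    "LN": ("LNi", "LNc"),
    "VPN": ("VPNi", "VPNc"),
}
FC_CORTEX = {"FC_CG": "CG", "FC_RS": "RS"}
POST_TIMEPOINTS = ("W2", "M2", "M6")


def default_cohort(seed: int = 7, **overrides) -> Cohort:
    """The default study conditions with a caller-chosen seed."""
    return generate_cohort(SynthConfig(seed=seed, **overrides))


def process_cohort_fc(cohort: Cohort):
    """Run the motion-aware FC chain for every scan.

    Post-injury scans first pass the lesion-artifact exclusion: mean images
    are globally normalized, compared with baseline, and ROIs losing more
    than the allowed voxel fraction are invalidated before connectivity.

    Returns ``(fc_table, qc_table)``: tidy edges (animal, group, timepoint,
    roi_a, roi_b, r, z) and per-scan QC (mean/max FD over the scan, window
    start, FD within the window, discard flag, per-ROI validity count).
    """
    phantom = cohort.phantom
    brain = phantom.brain_mask
    normalized_baselines = {
        s.subject_id: lesionmask.global_normalize(s.scans["BL"].mean_volume, brain)
        for s in cohort.subjects
    }
    gbm = lesionmask.grand_baseline_mean(list(normalized_baselines.values()), brain)
    fc_rows, qc_rows = [], []
    for subject in cohort.subjects:
        base_norm = normalized_baselines[subject.subject_id]
        for tp, scan in subject.scans.items():
            ts = scan.timeseries
            n_invalid = 0
            if tp != "BL":
                post_norm = lesionmask.global_normalize(scan.mean_volume, brain)
                excluded = lesionmask.exclusion_mask(post_norm, base_norm, gbm)
                validity = lesionmask.roi_validity(excluded, phantom.roi_masks)
                flags = np.array([validity.valid[r] for r in ts.roi_names])
                n_invalid = int((~flags).sum())
                ts = motionfc.ROITimeSeriesSet(
                    roi_names=ts.roi_names, series=ts.series, valid=flags
                )
            fd, window, qc, fc = motionfc.connectivity_pipeline(ts, scan.motion, scan.qc)
            qc_rows.append(
                {
                    "animal": subject.subject_id,
                    "group": subject.group,
                    "timepoint": tp,
                    "mean_fd_mm": fd.mean_fd,
                    "max_fd_mm": fd.max_fd,
                    "window_start": window.start,
                    "window_mean_fd_mm": window.criterion_value,
                    "window_max_fd_mm": float(fd.fd[window.slice].max()),
                    "n_components_removed": qc.n_removed,
                    "discarded": qc.discarded,
                    "n_invalid_rois": n_invalid,
                }
            )
            if fc is None:
                continue
            names = fc.roi_names
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    fc_rows.append(
                        {
                            "animal": subject.subject_id,
                            "group": subject.group,
                            "timepoint": tp,
                            "roi_a": names[i],
                            "roi_b": names[j],
                            "r": fc.r[i, j],
                            "z": fc.z[i, j],
                        }
                    )
    return pd.DataFrame(fc_rows), pd.DataFrame(qc_rows)


def process_cohort_pet(cohort: Cohort) -> pd.DataFrame:
    """Injection QC, late-frame summation, normalization, ROI uptake.

    Returns one row per (animal, roi) with the normalized uptake and the
    injection QC outcome; failed injections keep their rows (flagged) so
    the exclusion is auditable, but downstream analyses drop them.
    """
    phantom = cohort.phantom
    rows = []
    for subject in cohort.subjects:
        if subject.pet is None:
            continue
        ok, _ = petquant.injection_qc(subject.pet, phantom.body_mask)
        summed = petquant.sum_frames(subject.pet)
        u_vol, _ = petquant.normalize_uptake(
            summed, phantom.body_mask, subject.pet.voxel_volume_ml
        )
        table = petquant.roi_uptake(u_vol, phantom.roi_masks)
        for rec in table.itertuples():
            rows.append(
                {
                    "animal": subject.subject_id,
                    "group": subject.group,
                    "roi": rec.roi,
                    "u_feppa": rec.u_feppa,
                    "injection_ok": ok,
                }
            )
    return pd.DataFrame(rows)


def process_cohort_dti(cohort: Cohort) -> pd.DataFrame:
    """Tensor fit, scalar maps, ROI means for every diffusion acquisition."""
    phantom = cohort.phantom
    rows = []
    for subject in cohort.subjects:
        for tp, rec in subject.dwi.items():
            fit = dtimetrics.fit_tensor_loglinear(
                np.asarray(rec.signals, dtype=float), rec.protocol
            )
            evals = dtimetrics.tensor_eigenvalues(fit.tensors)
            scalars = dtimetrics.tensor_scalars(evals)
            table = dtimetrics.roi_metric_means(scalars, phantom.roi_masks)
            table = table.assign(
                animal=subject.subject_id, group=subject.group, timepoint=tp
            )
            rows.append(table)
    return pd.concat(rows, ignore_index=True)


def process_cohort_histology(
    cohort: Cohort, thresholds: histoquant.ClassThresholds
) -> pd.DataFrame:
    """Classify nuclei, compute densities and corrected OD, average sections.

    Returns one row per (animal, roi) with section-averaged cd_ne, cd_gl
    (cells/mm^2) and corrected OD.
    """
    rows = []
    for subject in cohort.subjects:
        if subject.histology is None:
            continue
        classified = histoquant.classify_nuclei(subject.histology.nuclei, thresholds)
        dens = histoquant.density_table(classified, subject.histology.roi_areas)
        dens = dens[dens["section"] == "mean"].set_index("roi")
        od = histoquant.od_table(subject.histology.od)
        od = od[od["section"] == "mean"].set_index("roi")
        for roi in dens.index:
            rows.append(
                {
                    "animal": subject.subject_id,
                    "group": subject.group,
                    "roi": roi,
                    "cd_ne": float(dens.loc[roi, "cd_ne"]),
                    "cd_gl": float(dens.loc[roi, "cd_gl"]),
                    "od": float(od.loc[roi, "od"]),
                }
            )
    return pd.DataFrame(rows)


def _fc_z_lookup(fc_df: pd.DataFrame) -> dict:
    """(animal, timepoint, roi_x, roi_y) -> Fisher z (both orders)."""
    out = {}
    for rec in fc_df.itertuples():
        out[(rec.animal, rec.timepoint, rec.roi_a, rec.roi_b)] = rec.z
        out[(rec.animal, rec.timepoint, rec.roi_b, rec.roi_a)] = rec.z
    return out


def cohort_delta_table(
    cohort: Cohort,
    fc_df: pd.DataFrame,
    pet_df: pd.DataFrame,
    dti_df: pd.DataFrame,
    histo_df: pd.DataFrame,
) -> pd.DataFrame:
    """Per-animal ipsilateral-contralateral deltas for every metric.

    Tidy schema: animal, group, nucleus (LN/VPN), metric, timepoint, delta.
    Uptake deltas come from the subacute PET (W2, successful injections
    only); FC deltas are differences of Fisher-z values; histology deltas
    carry the terminal timepoint label. Missing inputs propagate as NaN.
    """
    rows = []
    pet_ok = pet_df[pet_df["injection_ok"]] if len(pet_df) else pet_df
    z_of = _fc_z_lookup(fc_df)

    for subject in cohort.subjects:
        a, g = subject.subject_id, subject.group
        for nucleus, (ipsi, contra) in NUCLEUS_SIDES.items():
            # PET uptake asymmetry (subacute)
            sub = pet_ok[pet_ok["animal"] == a] if len(pet_ok) else pet_ok
            if len(sub):
                u = sub.set_index("roi")["u_feppa"]
                if ipsi in u.index and contra in u.index:
                    rows.append(
                        dict(animal=a, group=g, nucleus=nucleus, metric="U_FEPPA",
                             timepoint="W2",
                             delta=latstats.delta_metric(u[ipsi], u[contra]))
                    )
            # diffusion metrics
            sub = dti_df[dti_df["animal"] == a]
            for tp in sub["timepoint"].unique():
                at_tp = sub[sub["timepoint"] == tp].set_index(["roi", "metric"])["value"]
                for metric in dtimetrics.SCALAR_NAMES:
                    if (ipsi, metric) in at_tp.index and (contra, metric) in at_tp.index:
                        rows.append(
                            dict(animal=a, group=g, nucleus=nucleus, metric=metric,
                                 timepoint=tp,
                                 delta=latstats.delta_metric(
                                     at_tp[(ipsi, metric)], at_tp[(contra, metric)]))
                        )
            # connectivity (Fisher-z differences)
            for tp in POST_TIMEPOINTS:
                for fc_metric, cortex in FC_CORTEX.items():
                    zi = z_of.get((a, tp, cortex, ipsi), np.nan)
                    zc = z_of.get((a, tp, cortex, contra), np.nan)
                    rows.append(
                        dict(animal=a, group=g, nucleus=nucleus, metric=fc_metric,
                             timepoint=tp, delta=latstats.delta_metric(zi, zc))
                    )
            # terminal histology
            sub = histo_df[histo_df["animal"] == a] if len(histo_df) else histo_df
            if len(sub):
                h = sub.set_index("roi")
                if ipsi in h.index and contra in h.index:
                    for metric, col in (("CD_ne", "cd_ne"), ("CD_gl", "cd_gl"),
                                        ("OD", "od")):
                        rows.append(
                            dict(animal=a, group=g, nucleus=nucleus, metric=metric,
                                 timepoint=HISTO_TIMEPOINT,
                                 delta=latstats.delta_metric(
                                     h.loc[ipsi, col], h.loc[contra, col]))
                        )
    return pd.DataFrame(rows)


def derive_training_thresholds(config: SynthConfig) -> histoquant.ClassThresholds:
    """Classification thresholds from the cohort's curated training sample."""
    seq = np.random.SeedSequence(config.seed, spawn_key=(997,))
    neuronal, glial = generate_training_nuclei(config, np.random.default_rng(seq))
    return histoquant.derive_class_thresholds(neuronal, glial)


def run_pipeline(cohort: Cohort) -> dict:
    """Full analysis chain on one cohort.

    Returns a dict with the per-modality tables (``fc``, ``qc``, ``pet``,
    ``dti``, ``histology``), the lateralization ``deltas``, and the
    uptake-asymmetry ``correlations`` grid.
    """
    fc_df, qc_df = process_cohort_fc(cohort)
    pet_df = process_cohort_pet(cohort)
    dti_df = process_cohort_dti(cohort)
    thresholds = derive_training_thresholds(cohort.config)
    histo_df = process_cohort_histology(cohort, thresholds)
    deltas = cohort_delta_table(cohort, fc_df, pet_df, dti_df, histo_df)
    correlations = latstats.build_delta_correlation_matrix(deltas)
    return {
        "fc": fc_df,
        "qc": qc_df,
        "pet": pet_df,
        "dti": dti_df,
        "histology": histo_df,
        "thresholds": thresholds,
        "deltas": deltas,
        "correlations": correlations,
    }


def pattern_agreement(correlations: pd.DataFrame, pattern: dict) -> float:
    """Fraction of correlation-grid cells whose significance matches the
    generating coupling pattern."""
    indexed = correlations.set_index(["nucleus", "metric", "timepoint"])
    hits, total = 0, 0
    for (nucleus, metric, tp), coupled in pattern.items():
        total += 1
        try:
            sig = bool(indexed.loc[(nucleus, metric, tp), "significant"])
        except KeyError:
            sig = False
        hits += sig == coupled
    if total == 0:
        raise ValueError("empty coupling pattern")
    return hits / total
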