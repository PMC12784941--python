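# corticothal

Quantification pipeline for longitudinal multimodal imaging of
corticothalamic injury in a rat model of traumatic brain injury (TBI),
for researchers studying how secondary thalamic neuroinflammation
relates to connectivity disruption. The package implements:

* **Resting-state fMRI connectivity** with motion-aware segment
  selection: framewise displacement FD[t] = Σ|Δtrans| + r·Σ|Δrot|,
  selection of the least-motion 300-volume window (first 5 min
  excluded), component-removal scan discard (> 20/30), motion
  regression, and Pearson/Fisher-z ROI connectivity.
* **Lesion-artifact exclusion**: voxels whose normalized mean-image
  change from baseline exceeds 2.5 × the grand mean baseline intensity
  are excluded; ROIs losing > 30 % of voxels are omitted.
* **TSPO-PET uptake**: 15–60 min frame summation, normalization to
  rostro-thoracic body uptake, U = 100·c / Σ_body(c·v) in %/ml, and
  time-activity-curve injection QC.
* **DTI scalars**: log-linear tensor fit of S = S0·exp(−b gᵀDg) and the
  standard scalars MD = (λ1+λ2+λ3)/3, AD = λ1, RD = (λ2+λ3)/2,
  FA = √(3/2)·‖λ−MD‖/‖λ‖.
* **Histological quantification**: nuclear-area classification with
  mean ± 2 SD training thresholds, cell density CD = CC/ROI_area, and
  corrected optical density OD = (I_ROI − I_BG)/I_WM, averaged over
  three sections.
* **Lateralization statistics**: per-animal Δ = ipsi − contra metrics,
  two-sample and paired t-tests with Benjamini–Hochberg FDR (q), and
  the Spearman correlation grid of ΔU_FEPPA against every other Δ.
* **A synthetic cohort generator** (36 TBI + 11 SHAM, timepoints
  BL/W2/M2/M6, ROIs VPNi/VPNc/LNi/LNc/RS/CG) with known ground truth,
  so every stage is testable without the original raw data. A latent
  per-animal inflammation severity couples ipsilateral PET uptake,
  diffusivity, histology and (at M2 only) connectivity asymmetries.

See `docs/methods.md` for models, parameter choices and limitations.

## Worked example

The numbered scripts under `analysis/` run the full study on the
default synthetic cohort and write tidy tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/06_lateralization_correlations.py
```

`01` prints the cohort bookkeeping and motion summary:

```
cohort: 47 animals (36 TBI, 11 SHAM)
PET at W2: 34 scanned, 8 faulty injections, histology subset: 20
mean FD: 0.0293 +/- 0.0005 mm
mean within-window max FD: 0.1444 mm
scans retained: 176/188 (93.62%)
```

i.e. head motion is small (≈ 0.03 mm per volume), the least-motion
windows contain at worst ≈ 0.14 mm excursions, and 12 scans fail the
component-removal rule. `06` builds the Δ-correlation grid (excerpt):

```
Delta U_FEPPA correlations, LN:
 * MD@M2: rho=+0.943 (p=6.33e-13, n=26)
 * RD@M6: rho=+0.942 (p=7.27e-13, n=26)
   FC_CG@W2: rho=+0.174 (p=0.416, n=24)
 * FC_CG@M2: rho=-0.745 (p=1.91e-05, n=25)
   FC_CG@M6: rho=+0.121 (p=0.565, n=25)
 * CD_gl@M8: rho=+0.932 (p=2.21e-09, n=20)

agreement with the generating coupling pattern: 1.000 (34/34 cells)
```

Animals with higher subacute uptake asymmetry show larger chronic
diffusivity and glial-density asymmetries; connectivity asymmetry
correlates with uptake only at two months — exactly the pattern the
generator encodes, recovered through the full measurement chain
(scripts `02`–`05` print the per-modality group analyses).

The library surface mirrors the pipeline: `corticothal.motionfc`,
`.lesionmask`, `.petquant`, `.dtimetrics`, `.histoquant`, `.latstats`,
`.synth`, `.pipeline`. For example:

```python
from corticothal import motionfc, pipeline

cohort = pipeline.default_cohort(seed=7)
scan = cohort.subjects[0].scans["W2"]
fd, window, qc, fc = motionfc.connectivity_pipeline(
    scan.timeseries, scan.motion, scan.qc
)
print(window.start, fc.pair("CG", "LNi"))
```

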