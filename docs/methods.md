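# Methods

`corticothal` quantifies longitudinal multimodal lateralization after a
focal cortical injury in a rat model: resting-state functional
connectivity (FC) between thalamic nuclei and midline cortex, TSPO-PET
tracer uptake, diffusion-tensor scalars, and histological cell densities
and myelin optical density, tied together by an ipsilateral-minus-
contralateral (Δ) correlation analysis. Because the original raw data
are not redistributed here, the package ships a synthetic-cohort
generator with known ground truth; every analysis stage is exercised and
validated against that generator.

## Study structure being emulated

Two groups (36 TBI, 11 SHAM = 47 animals) over four timepoints: baseline
(BL), two weeks (W2), two months (M2) and six months (M6) post-injury,
with terminal histology at eight months (M8). Six regions of interest:
ipsi- and contralateral ventral posterior nucleus (VPNi/VPNc) and
lateral nuclei (LNi/LNc) of the thalamus, plus retrosplenial (RS) and
cingulate (CG) cortex. PET is acquired at W2 for a subgroup (25 TBI, 9
SHAM); 7 TBI and 1 SHAM injections fail QC, leaving 26 analyzable scans.
Histology (3 sections per animal) covers 20 of the PET-successful
animals (14 TBI, 6 SHAM). The suffixes i/c denote the injured and
uninjured hemisphere.

## Functional connectivity chain (`motionfc`, `lesionmask`)

1. **Framewise displacement (FD).** From the six rigid-body parameters:
   FD[t] = Σ|Δtranslation| + r·Σ|Δrotation|, with rotation radius
   r = 5 mm (rat-brain scale, configurable) converting radians to arc
   millimetres; FD[0] = 0. The exact image-based FD computation used
   upstream in registration software is not reproducible from parameters
   alone, so this transparent, oracle-checkable form is the package's
   stated definition.
2. **Least-motion segment.** The contiguous 300-volume window (5 min at
   TR = 1 s) starting at or after volume 300 (the first 5 min are
   excluded to avoid lingering induction-anesthesia effects) that
   minimizes mean FD; ties break to the earliest start. Mean FD is used
   as the criterion because it is also the reported motion summary.
3. **Scan discard.** A scan is dropped entirely when the upstream
   component-based cleanup removed strictly more than 20 of 30
   components.
4. **Lesion-artifact exclusion.** Mean images per timepoint are divided
   by their in-brain-mask mean ("global intensity" normalization, the
   simplest scale normalization consistent with expressing the threshold
   in baseline-mean units). Voxels whose **absolute** normalized change
   from baseline exceeds 2.5 × the grand mean baseline intensity
   (in-mask mean of normalized baselines averaged over the cohort — 1 by
   construction under this normalization) are excluded; an ROI losing
   strictly more than 30 % of its voxels is omitted. The absolute
   difference is used because hypo- (microbleed) and hyperintense
   (CSF/edema) anomalies are both artifacts. Excluded voxels are also
   dropped from the ROI-mean series of retained ROIs. Signedness and the
   normalization convention are configurable since the operational
   definition admits variants.
5. **Motion regression and correlation.** Within the selected window
   only (the analyzed data), each series is OLS-regressed on an
   intercept plus the six motion parameters; constant regressors are
   dropped with a warning. Pairwise Pearson correlations of the
   residual ROI series form the FC matrix; Fisher z = atanh(r) with |r|
   clipped at 1 − 1e−7 keeps z finite. Entries of invalid or
   zero-variance ROIs are missing (NaN), never zero. Volume indexing is
   0-based with half-open windows.

## PET quantification (`petquant`)

Frames overlapping 15–60 min post-injection are summed with
duration weighting (partial frames weighted by overlap), the summed map
is normalized to total in-field-of-view body activity, and uptake is
reported as a percentage of total rostro-thoracic uptake per ml (%/ml):
U = 100·c / Σ_body(c·v). The body-mask integral of U is exactly 100 and
U is invariant to injected dose. Faulty tail-vein injections are flagged
from the whole-mask time-activity curve: a successful bolus rises
monotonically over the first 5 min; a drop larger than 5 % of the curve
maximum between consecutive early frames fails QC (threshold
configurable — no quantitative criterion is published, so this is the
package's operational definition). Note a property of relative
normalization worth remembering when reading group tables: elevating
uptake in one region necessarily depresses the normalized values of all
others slightly.

## Diffusion metrics (`dtimetrics`)

Signals follow S = S0·exp(−b gᵀDg) (single shell, b = 2800 s/mm², 42
uniform directions + 4 b = 0 images). The tensor is fitted by log-linear
least squares — exactly invertible on noise-free data, which makes
round-trip tests sharp; non-positive signals are clipped to machine
epsilon and counted. Scalars from descending eigenvalues λ1 ≥ λ2 ≥ λ3:
MD = (λ1+λ2+λ3)/3, AD = λ1, RD = (λ2+λ3)/2,
FA = √(3/2)·‖λ−MD‖/‖λ‖ ∈ [0, 1] (FA := 0 for a zero tensor). Negative
eigenvalues from noisy fits are clipped to 0 for scalar computation and
flagged. At this b-value the Rician noise floor biases high-diffusivity
voxels; at SNR 30 the MD bias stays under 5 % and a configured 1.25×
ROI contrast is recovered within 5 % (both tested). Tractography-based
tract ROIs are out of scope; ROI masks are inputs.

## Histology (`histoquant`)

Classification thresholds are mean ± k·SD (k = 2, sample SD with n−1)
of a curated training sample per class; with the study-scale training
distributions (966 neuronal nuclei ≈ N(133.5, 40.75²) µm², 731 glial ≈
N(21, 6.5²) µm², chosen so the derived intervals reproduce the working
ranges 52–215 and 8–34 µm²) the intervals are disjoint. Interval
membership is closed on both ends; areas in neither interval are
unclassified and excluded from both counts; should intervals overlap,
ties go to the smaller standardized distance (cannot occur with the
default thresholds — defined for robustness). Cell density is
CD = count / ROI area, reported per mm² (ROI areas supplied in µm² are
converted; 1 mm² = 1e6 µm²). Myelin staining is corrected as
OD = (I_ROI − I_BG)/I_WM with background and white-matter references
from the same section; OD may legitimately be negative and is flagged,
and the formula is applied to whatever intensity scale is supplied.
Metrics are averaged across the three analysed sections; deviations
from three are logged, not fatal.

## Statistics (`latstats`)

Lateralization is Δx = x(ipsi) − x(contra) per animal; FC deltas are
differences of Fisher-z values (ΔFC_CG(LN) = z(CG,LNi) − z(CG,LNc)).
Missing values propagate, never imputed. Group contrasts use Student's
two-sample t (equal variance, the default reading of an unqualified
"two-sample t-test"; Welch is an option); within-group contrasts a
paired t. Benjamini–Hochberg adjusted p-values (q) are computed per
analysis table (one family per timepoint matrix) — the family
definition is configurable since it is a reporting convention. Spearman
correlations (mid-ranks for ties) relate ΔU_FEPPA to every other Δ;
p-values use the t approximation with an exact permutation option for
n ≤ 10, and the least-squares line on the original scale accompanies
each correlation for scatter overlays. Correlation-grid significance is
p < 0.05 uncorrected, as such grids are conventionally annotated; both
TBI and SHAM animals enter the grid.

## Synthetic cohort (`synth`)

No generative model is published for these data, so the generator uses
the simplest processes that make the downstream estimators' behaviour
analysable:

* **fMRI.** ROI series are unit-variance Gaussian AR(1) processes
  (φ = 0.3) mixed by the symmetric square root of a target correlation
  matrix, so the population instantaneous correlation equals the target
  exactly. Baseline connectivity: 0.45 between thalamic nuclei, 0.40
  corticothalamic, 0.60 RS–CG (checked positive semidefinite). A small
  portion of the motion regressors leaks into the series (gain 0.2) so
  motion regression is consequential.
* **Injury effects on FC.** At W2 TBI animals have a bilateral
  corticothalamic deficit (−0.10 in r) with a small, subject-variable,
  sign-free ipsilateral excess (mean −0.03, SD 0.06) — the subacute
  asymmetry exists on average but is deliberately *not* driven by the
  latent severity, reflecting the observation that the largest FC
  changes need not track inflammation; at M2 the ipsilateral deficit is
  proportional to the latent severity (0.15·L, the only FC–severity
  coupling); by M6 deficits largely resolve (−0.03). SHAM animals get a
  small retrosplenial increase at W2 (craniotomy effect). Per-subject
  matrices are projected back to the nearest unit-diagonal PSD matrix.
* **Latent severity.** Each subject carries L ~ N(1, 0.4²) truncated at
  0.2 (TBI) or ≈ 0 (SHAM), the common cause coupling modalities.
* **Motion.** Translation jitter SD 0.0075 mm per axis (rotations at
  10 % of that scale via the 5 mm radius), giving mean FD ≈ 0.029 mm;
  step-like position spikes at rate 0.01/volume with amplitude
  ≈ 0.15 mm reproduce a within-window maximum FD of ≈ 0.15 mm. Spike
  indices are ground truth.
* **Scan QC.** Component-removal counts are drawn so that ≈ 8.5 % of
  scans exceed the 20-of-30 discard rule, matching the study-scale
  retention bookkeeping.
* **Anatomy/lesion.** A 24×24×12 box phantom with disjoint ROI boxes; a
  growing hyperintense spherical lesion (4 × brain-mean intensity, i.e.
  > 2.5 × after normalization) near RS/LNi drives the exclusion rule
  without omitting ROIs at default settings.
* **PET.** A spatial concentration map (thalamus 1.8, cortex 1.5, brain
  1.2, body 1.0; ipsilateral thalamus × (1 + 0.5·L)) modulated by a
  monotone-rise/plateau time-activity curve over 0–70 min; faulty
  injections get an early-peak/washout curve that the QC flags. Total
  body volume 150 ml sets the %/ml scale (uptake ≈ 0.9–1.6 %/ml).
* **DTI.** Thalamic eigenvalues (1.05, 0.65, 0.55)·10⁻³ mm²/s
  (MD 0.75·10⁻³, FA ≈ 0.33); ipsilateral thalamic eigenvalues scale by
  (1 + c_MD·L) with c_MD = 0.25 (M2) and 0.30 (M6), plus an extra
  radial-only factor (1 + 0.10·L) so anisotropy falls with severity —
  gliosis and fiber disorganization reduce FA, and the high-b Rician
  noise floor pushes the measured FA the same way. Voxel orientations
  are random; Rician noise at SNR 30.
* **Histology.** Contralateral densities 650 (neuronal) and 900 (glial)
  cells/mm²; ipsilateral factors (1 − 0.25·L) and (1 + 0.6·L); OD 0.5
  contralateral, (1 − 0.25·L) ipsilateral, with a 0.95 staining-artifact
  factor on RSi in **both** groups (emulating the orientation-branding
  artifact). Counts are Poisson over noisy section areas (~1.5 mm²);
  areas are per-class truncated Gaussians plus ~3 % contaminant
  detections in the inter-class gap. True class labels live in the
  ground-truth sidecar, never in observed tables.

Everything is a pure function of (config, seed); subjects use spawned
independent substreams. The expected coupling pattern
(`expected_coupling_pattern`) records which Δ-correlation cells the
generator ties to L: MD/AD/RD/FA at M2 and M6, CD_ne/CD_gl/OD at M8,
and FC_CG/FC_RS at M2 only.

### What the generator does not emulate

Hemodynamic response and physiology confounds, k-space/EPI artifacts,
registration error, PET kinetics and partial-volume effects, anatomical
variability, and realistic lesion morphology. Passing tests therefore
demonstrate the correctness and calibration of the estimators under the
stated statistical structure, not robustness to real-data artifacts.

## Verification strategy and problem sizes

Unit tests check each operation against independent oracles
(element-wise FD recomputation, exhaustive window search, brute-force
step-up FDR, rank-then-Pearson correlation, hand-computed t statistics)
and property tests (hypothesis, derandomized) cover invariants: FD ≥ 0,
AD ≥ MD ≥ RD, FA scale invariance, OD shift invariance, Δ antisymmetry,
BH monotonicity. Calibration suites use 1,000 random FD traces for the
window oracle, 50 replicate scans per condition for FC recovery (mean z
within 3 standard errors of atanh r), 10,000 null replicates for t-test
type-I error, 1,000 replicate null delta tables for the correlation
grid's false-positive rate, and 20 seeded replicate cohorts for
end-to-end pattern recovery, where a replicate counts as recovered when
cell-wise significance agreement with the generating pattern is ≥ 0.9
(the grid has 34 cells; the margin absorbs the nominal 5 % false
positives among uncoupled cells without letting a missed coupled effect
pass unnoticed). These sizes keep the default suite within a few
minutes on one CPU while leaving the statistical margins comfortable.

## Known limitations

* The FD formula and the "least motion" criterion are stated package
  definitions; the upstream study pipeline's exact computations are not
  recoverable from the publication.
* The lesion-exclusion threshold's normalization and signedness are
  operational choices exposed as configuration.
* Relative (%/ml) PET normalization induces small anti-correlations
  between regions; interpret non-thalamic group differences accordingly.
* The log-linear tensor fit is unweighted; at very low SNR a weighted or
  nonlinear fit would be preferable.
* FDR families follow the per-table convention; other family choices
  change q-values.
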