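# Methods

## Scope and model overview

`megspect` analyses resting-state MEG at the cortical source level and
evaluates the full chain on simulated cohorts with known ground truth.
The analysis model is:

* sensor data **b**(t) = **L s**(t) + **n**(t), with **L** the lead
  field of current dipoles in a homogeneous conducting sphere (Sarvas
  closed form), sources constrained to fixed orientations along the
  cortical normals, and white sensor noise **n**;
* a linear inverse **K** = **W L**ᵀ(**L W L**ᵀ + λ²**I**)⁻¹ (weighted
  minimum norm).  **W** is diagonal with
  W_v = ‖L_v‖^(−2·depth_exponent); λ² = trace(**L W L**ᵀ)/(n_ch·snr²);
* regional *absolute power* in a band = mean over epochs, samples and
  region vertices of |**K b**(t)| after zero-phase band filtering — an
  amplitude (A·m), not a power spectral density;
* six value types per (band, region): absolute power EC/EO, their WCN
  z-scores across the 68 regions, the EC−EO difference, and its WCN;
* Welch two-tailed tests per cell at the Bonferroni threshold
  α/(68·5) = 0.000147, applied within each 340-cell value-type family
  (the divisor counts regions and bands, not value types);
* a degree-2 polynomial-kernel SVM with subject-level stratified 6-fold
  cross-validation; AD is the positive class.

## Key parameters

| parameter | default | units | notes |
|---|---|---|---|
| bands | θ1 4–6, θ2 6–8, α1 8–10, α2 10–13, β 13–20 | Hz | δ and γ excluded from the analysis range |
| artifact threshold | 10e-12 | T | peak amplitude; 2-s blocks excised |
| epoch length | 2 | s | rejection block = epoch, so the two commute |
| filter | Butterworth order 4, forward–backward | — | ≤1 s reflection padding |
| snr (regularization) | 3 | — | λ² = trace(LWLᵀ)/(n·snr²) |
| depth_exponent | 0.5 | — | 0 disables depth weighting |
| WCN denominator | population SD (N) | — | sample SD (N−1) available via `ddof` |
| SVM | degree 2, C = 1, offset 1, scale √n_features | — | standardization on training folds |
| cohort | 20 AD / 27 NC | subjects | EC and EO per subject |

## The synthetic generator

The generator emulates the *statistical structure* the analysis assumes,
not MEG hardware:

* **Geometry.** Sensors are quasi-uniform point magnetometers (radial
  sensing) on a helmet cap at 12 cm; the "cortex" is a quasi-uniform
  shell at 0.8 × the 9-cm conductor radius restricted to the
  helmet-covered zone (z/r > −0.35), because real cortex occupies the
  upper head and a full source sphere would place sources outside any
  sensor coverage.  Source orientations are tangentially biased (random
  tangential direction plus N(0, 0.3) radial component): MEG-visible
  cortical currents are predominantly tangential, and exactly radial
  sources are silent in a spherical conductor.  The parcellation is a
  left/right-symmetric 68-patch Voronoi partition carrying
  Desikan–Killiany labels.
* **Activity.** Each vertex carries a sum over the five bands of
  band-limited Gaussian processes plus a 1/f floor (0.3 nA·m RMS).
  Band limiting applies the squared magnitude response of the *same*
  zero-phase Butterworth filters the analysis uses, so synthesis and
  analysis band edges agree exactly; the independent band processes are
  synthesized jointly as one Gaussian spectrum per vertex (equal in
  distribution to their sum, one FFT per recording).  Band RMS
  amplitudes per region: θ1 0.80/0.72, θ2 0.80/0.72, α1 2.00/1.00,
  α2 1.50/0.85, β 0.60/0.55 nA·m (EC/EO) — alpha dominates and reacts
  strongly to eye opening, every band is mildly higher eyes-closed.
* **Group effect.** The AD group's α1 amplitude in the right
  supramarginal region is multiplied by 1.4 under both conditions —
  about +2 between-subject SD at the default between-subject
  variability, which is a log-normal multiplier per (band, region) with
  CV 0.2, drawn once per subject and shared across conditions (a stable
  individual trait, so EC and EO move together).
* **Noise.** White sensor noise (50 fT SD) and Poisson-timed 100-ms
  boxcar artifacts (default 1/min, 12 pT, random channel and sign) that
  the 10-pT rejection reliably catches; simulated signals peak well
  below 10 pT.

What the generator does **not** emulate: cardiac/ocular components and
their PCA/ICA removal, gradiometer pickup geometry, head movement,
correlated (1/f-structured) sensor noise, vendor file formats, and any
anatomical realism beyond the zone/parcellation structure.  Passing
tests therefore demonstrate the correctness and calibration of the
analysis chain under its own model assumptions, not performance on real
recordings.

## Numerical choices

* Rejection scans ceil(duration/2 s) blocks aligned to t = 0, the
  trailing partial block included; epoching floors to complete epochs.
* `wcn_normalize` raises on zero dispersion (SD ≤ 1e-12 of the largest
  magnitude) instead of returning silent zeros.
* Lead-field columns that are numerically zero (silent radial sources)
  receive zero depth weight and hence zero estimates, rather than an
  unbounded weight.
* Degenerate test cells (both groups constant) report p = 1 when the
  means agree and p = 0 otherwise.
* Welch's unequal-variance t is the default test; Student's t and
  Mann–Whitney are selectable.
* The SVM kernel is (1 + x·y/s²)² with s = √n_features by default: for
  standardized features the kernel argument is then a correlation-like
  O(1) quantity independent of dimensionality.  With s = 1 and 2,040
  features the Gram matrix is dominated by squared-norm variation
  (entries ~4×10⁶) and cross-validation degenerates to majority-class
  predictions; a numeric scale remains available in the configuration.
* TSV outputs use a fixed `%.12g` float format and JSON outputs sorted
  keys, so identical configurations produce byte-identical artifacts.

## Evaluation sizes

Recovery and calibration studies run at reduced, documented sizes chosen
as the package's standard evaluation scale: 64 channels / 500 vertices
for single-source localization; 64 channels / 250 vertices / 100 Hz /
30-s recordings for replicate cohort studies; 200 replicates on
ground-truth amplitude tables (no forward/inverse stage) for null
calibration.  The acquisition-scale setup (160 channels, 15,000
vertices, 1000 Hz, 120 s) is available via `scale: paper` in the run
configuration.

## Known limitations

* **Inverse leakage attenuates regional effects.**  A minimum-norm
  regional estimate mixes in neighbouring regions' activity; measured
  between-group effect sizes for a single-region amplitude elevation are
  attenuated to roughly half their ground-truth noncentrality at these
  channel counts.  Consequently a +2-SD single-cell effect that is
  detected in ≈80–100% of ground-truth-level replicates reaches the
  0.000147 threshold in only ≈40–60% of full-pipeline replicates.  This
  is a property of regularized distributed inverses, not of the
  statistics; the test suite asserts both levels separately.
* After per-feature standardization, a single feature's class separation
  is bounded by 1/√(p(1−p)) ≈ 4 SD regardless of the raw effect, and
  with ~2,000 noise features at n = 47 the weight-estimation noise
  bounds any kernel classifier's cross-validated accuracy well below 1;
  the classifier sanity experiment therefore uses 100-feature cohorts,
  where recovery is exact.
* The spherical single-shell forward model coincides with
  overlapping-spheres approaches only for a spherical head; real-head
  accuracy is out of scope.
* Welch tests are mildly conservative/anticonservative in the extreme
  tail for skewed (log-normal) data; the null suite verifies the
  family-wise error empirically at the study threshold.
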