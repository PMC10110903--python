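# Methods

This note documents the models, conventions and numerical choices behind
`desep`: a pipeline that predicts survival outcomes after lung SBRT from a
segmentation network's latent features, exercised entirely on synthetic
tumor phantoms.

## Pipeline overview

Three phases:

1. **Segmentation.** A 3D U-Net is trained on tumor-centered crops with
   binary tumor masks (per-voxel cross-entropy, Adam). No outcome
   information enters this phase.
2. **Unsupervised feature reduction + supervised retention.** Each
   patient's crop is pushed through the trained encoder; the bottleneck
   activations are flattened into a latent feature vector. Features
   (columns of the cohort × features matrix) are clustered with k-medoids
   on their z-scored patient profiles; the cluster count is chosen by mean
   silhouette over a config grid; cluster medoids become the candidate
   features. An L1-penalized logistic regression against the binary 2-year
   outcome retains the outcome-associated medoids (penalty by minimum
   cross-validated deviance); an unpenalized logistic model is then fit on
   the retained features.
3. **Held-out evaluation.** Predicted 2-year event probabilities for the
   reserved test patients are dichotomized at 50% into low/high-risk
   groups; groups are compared with Kaplan-Meier curves, the log-rank
   test, a binary-covariate Cox hazard ratio, and Harrell's c computed on
   the continuous probabilities. Agreement between risk groupings and
   RECIST v1.1 dichotomies (progression vs non-progression) is measured
   with Cramér's φ.

Three endpoints are modeled in parallel — overall survival (OS),
disease-specific survival (DSS, censoring non-cancer deaths at the death
date), and local progression-free survival (LPFS) — sharing the
segmentation network and medoids but with endpoint-specific LASSO and
logistic fits.

## The U-Net

Four encoder blocks (3×3×3 convolution, ReLU, 2×2×2/stride-2 max pooling)
and a symmetric decoder (2×2×2/stride-2 transposed convolution, skip
concatenation, 3×3×3 convolution + ReLU), closed by a 1×1×1 convolution
with a two-channel softmax; the foreground probability is thresholded at
0.5 with ties assigned to foreground. Two presets:

| preset | input | encoder channels | bottleneck | latent length | lr |
|---|---|---|---|---|---|
| full scale | 96×96×48 (1 mm voxels) | 64/128/256/512 | 6×6×3×512 | 55 296 | 1e-4 |
| desk | 32×32×16 | 8/16/32/64 | 2×2×1×64 | 256 | 3e-3 |

The network and its training loop are implemented directly in numpy
(im2col convolutions, explicit backward passes, Adam with standard bias
correction); gradients are verified against finite differences in the test
suite. Weight initialization is He fan-in, seeded; training order is drawn
from the config seed, so runs are bit-reproducible. The desk preset exists
so that training completes in about half a minute on one CPU: with only
~150 optimizer steps in a 30-epoch desk run, the full-scale learning rate
of 1e-4 would leave the model far from converged, hence the larger desk
rate. Latent extraction runs the encoder only and does not retain backward
state, which keeps full-scale feature extraction under 1 GB of memory.

Intensities enter the network unnormalized by default: the synthetic
volumes (like calibrated CT units) carry meaning in their absolute scale,
and per-volume z-scoring — whose denominator is dominated by lesion size —
was found to erase the lesion-density information the prognostic stage
depends on. A per-volume z-score mode remains available in the config for
uncalibrated inputs.

The flattening order of the bottleneck is Fortran order over
(x, y, z, channel): x varies fastest, then y, z, channel. It is fixed and
documented because feature ids must remain stable between clustering,
retention, and prediction.

## Segmentation metrics

DSC = 2|A∩B|/(|A|+|B|); two empty masks score 1 (degenerate-case
convention). ASSD is the mean of the two directed average boundary
distances in mm, where boundary voxels are foreground voxels with a
face-adjacent background neighbor (array edges count as background) and
distances are between voxel centers scaled by the spacing; it is undefined
(an error) for empty masks.

## RECIST v1.1 engines

A single treated target lesion is tracked. Per follow-up scan, in
precedence order: CR if the measurement is 0; PD if it is ≥ nadir × 1.20
**and** (for diameters) ≥ nadir + 5 mm, where the nadir is the smallest
measurement so far including baseline; PR if ≤ baseline × 0.70; otherwise
SD. The final category is the worst over follow-ups (CR < PR < SD < PD),
dichotomized as PD vs non-PD for survival comparisons. The volumetric
engine applies the same structure to segmented volumes with preset
thresholds — ellipsoid (−30 %, +20 %) or spherical (−65 %, +73 %) — and no
absolute floor (no volumetric analogue of the 5 mm rule is defined). The
computer-based unidimensional engine measures the longest diameter within
an axial slice (maximum in-plane pairwise distance of foreground voxel
centers), never the 3D diagonal. An ellipsoid-model volume estimator
(π/6 · d₁d₂d₃) is available as an input transform for caliper-style
measurements.

## Survival statistics

Implemented from first principles and oracle-tested: the Kaplan-Meier
product-limit estimator; the two-group log-rank test with hypergeometric
variance; Cox regression for a single binary covariate by Newton
maximization of the Breslow partial likelihood (ties: Breslow; Wald 95 %
CI; monotone likelihoods are flagged and reported with an unbounded CI
rather than a spurious estimate); Harrell's c with the original
conventions (a pair is usable when the earlier time is an event, tied
event times are unusable, tied scores score one half); and Cramér's φ with
its χ²₁ p-value (χ² = n·φ²). Two-sided α = 0.05 throughout. An optional
seeded bootstrap provides a standard error for c.

## Synthetic phantom cohorts

Each subject carries one lesion: an ellipsoid with semi-axes drawn
uniformly from `radius_range`, centered in the grid, with smooth angular
spikes on its surface. A single per-lesion **severity** u ~ U(0,1) drives
the three correlated image expressions of aggressive morphology:

* spiculation — the radial spike field is scaled by
  u × `spiculation_strength` (peak-normalized so overlapping spikes cannot
  breach the 2-voxel grid margin);
* density — mean lesion contrast 1 + 0.8(u − 0.5), a subsolid-to-solid
  spectrum;
* heterogeneity — intra-lesional intensity texture of amplitude
  `texture_noise_sd` × (0.5 + u), half as a smooth random field (Gaussian
  blur, σ = 1.5 voxels, which survives pooling) and half voxel grain.

The raw morphology score is the RMS fractional radial perturbation
(quadrature over 256 Fibonacci-sphere directions) times (1 + u/2) — so a
spiculation-free cohort scores identically at the minimum — and is
z-scored across the cohort. Coupling all three appearances to one severity
axis is a deliberate stipulation: it guarantees the planted score has an
image expression that survives 1 mm voxelization and 16× downsampling,
which is precisely what the recovery experiments must test. What passing
those experiments shows is that the pipeline can find a morphology signal
a CNN can see; it does not show anything about the (much subtler) signal
in clinical CT.

**Outcomes.** Death times are exponential with hazard
h = `baseline_hazard` · exp(`log_hr_morphology` · z); censoring is an
independent exponential. Defaults — baseline hazard 0.35/yr, censoring
0.15/yr, 75 % of deaths cancer-related — are matched to the source
cohort's statistics (mean OS ≈ 2 years, ~54 % deceased, 40 of 51
known-cause deaths cancer-related). DSS events are the cancer-related
subset of deaths (non-cancer deaths censored); LPFS takes the earlier of
death and the trajectory-derived progression time. 2-year binary labels
are 1 for an event within 2 years, 0 for follow-up beyond 2 years, and
missing for event-free censoring before 2 years ("insufficient
follow-up"); missing-label patients are excluded from supervised fitting
but still receive predictions.

**Serial scans** follow the surveillance schedule (2 months after
treatment, then every 3 months; 4 follow-ups by default). Each patient is
a responder, stable, or progressor (default mix 0.35/0.30/0.35). Scale
factors are designed so that every scan sits deep inside one response
category with a ~2 mm margin for voxelization jitter — responders shrink
clearly past −30 % (possibly to full resolution, recorded as 0 mm/0 mm³),
stable lesions stay within ±5 %, progressors ramp below the 5 mm absolute
floor and then jump past both +20 % and +6.5 mm. Progressor growth is
applied to the in-plane axes only (the crop is thin along z), which leaves
the axial-diameter rules unaffected. True diameters are the baseline
mask's measured diameter scaled by the trajectory factor; true volumes are
voxel count × voxel volume of each rendered mask.

**Reproducibility.** Per-patient RNG streams derive from
(cohort seed, patient index, stage counter), so patient i is identical
regardless of cohort size and a (config, seed) pair reproduces a cohort
byte-for-byte, including its NIfTI/CSV serialization.

## Cross-validation and leakage

A seeded, outcome-stratified test fraction (default 25 %) is reserved
first; the remaining labeled patients form seeded stratified folds
(default 6) that drive the LASSO penalty choice. Standardization
constants, medoids, the penalty, and logistic weights are computed on
non-test patients only — a test perturbs held-out images and asserts the
fitted state is unchanged. Stratification degrades to plain folds with a
warning when a class is smaller than the fold count. Logistic fits use
Newton-Raphson to gradient norm < 1e-8; perfect separation is flagged and
the fit falls back to a light L2 penalty. A predicted probability exactly
at the 50 % cutoff is assigned to the high-risk group.

## Problem sizes and defaults

The desk-scale experiments use: a segmentation set of 30 phantoms (20
train / 10 held out, 30 epochs), prognostic cohorts of n = 120 with
planted log HR 1.5 per morphology SD, a silhouette grid of k ∈
{4, 8, 16, 24}, a penalty grid of 10 points in [1e-3, 3], and 20 null
replicates for calibration. These sizes keep a full run in a few minutes
on one CPU while leaving the planted-signal recovery comfortably above
chance; the full-scale preset is exercised for its architecture laws
(bottleneck 6×6×3×512 = 55 296 features) but not trained.

## Known limitations

* No respiratory motion, imaging artifacts, dose distributions, or PET
  channel; appearance is schematic, not Hounsfield-calibrated.
* Single-lesion tracking only: no sum-of-diameters bookkeeping, new-lesion
  detection, or nodal short-axis rules.
* The exact-PAM cluster stage subsamples very wide panels (default cap
  4096 features) before clustering; the full-scale 55 296-feature panel is
  therefore clustered on a seeded subsample.
* Cox fits are single-covariate (the risk-group contrast); no
  multivariable adjustment or competing-risks model for DSS.
* At full scale, `segment`'s decoder pass is memory-hungry (the im2col
  patch matrices of the concatenated decoder stages); latent extraction
  avoids this by running the encoder only.
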