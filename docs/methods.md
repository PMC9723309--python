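# Methods

`oscimap` re-creates, as a fully testable pipeline, a multivariate analysis
of resting-state EEG in Parkinson's disease (PD): spectral topographic
volumes are classified by a deliberately minimal 3D convolutional network,
the classifier's evidence is localized in scalp space and frequency with
Grad-CAM, and the localized oscillatory power is related to clinical scores
with linear mixed models. Because the original clinical cohorts are
external downloads, every stage here is exercised against a synthetic
cohort generator whose ground truth is known by construction.

## Synthetic cohorts

Each simulated recording is a sum of independent components, each driven by
its own child stream of one seed (so ablating one component, e.g. setting
the blink rate to zero, leaves the others bit-identical):

* **Background**: per channel, randomized-phase sinusoids with 1/f^χ
  amplitude (χ = 1 by default), high-passed at 0.5 Hz to mimic hardware
  coupling, normalized to an RMS of 10 µV. The Welch log-spectrum slope of
  the generated signal recovers χ, which is a tested invariant.
* **Cohort effects**: band-limited randomized-phase oscillations added at
  named electrode sets. The oscillation variance is calibrated to the
  *realized* background band variance of the same channel, so an effect
  with gain g multiplies band power by exactly 1 + g in expectation.
  Neighbouring electrodes within ~1 grid cell (planar radius 0.11) receive
  half the gain, a smooth falloff that makes localization recovery a fair
  test. The default signatures mirror the clinical contrast: controls
  carry occipitoparietal beta (13–30 Hz); patients off medication carry
  left-premotor/motor gamma (30–50 Hz) with weaker motor beta; patients on
  medication carry frontoparietal theta (4–8 Hz). Patient cohorts keep a
  reduced occipitoparietal beta (0.3 g) so that within-patient variation
  in that cluster exists for the association models.
* **Artifacts**: a 60 Hz sinusoid (2 µV); Gaussian-shaped blink transients
  (~150 µV, SD 0.12 s) confined to Fp1/Fp2/AF7/AF8 at 0.12 events/s, which
  gives roughly 85–90 % artifact-free 1-s trials, comparable to real
  resting recordings; optionally "dead-contact" bad channels (attenuated
  signal plus sensor noise) whose labels are carried as ground truth.
* **Clinical table**: per-subject effect gains are jittered around the
  class means (relative SD 0.25), and outcomes are linear in the
  standardized jitters: off-state UPDRS motor couples to occipitoparietal
  beta (ρ = −0.6), disease duration to motor beta (ρ = +0.6), and the
  on–off UPDRS change to on-state frontoparietal theta (ρ = −0.6); LEDD is
  drawn without any coupling as a built-in null. Marginal means and SDs
  (age 70 ± 9 y, UPDRS ~24 ± 8, duration 5.4 ± 4.1 y, LEDD 685 ± 452 mg,
  MMSE ≥ 26) match a typical moderate PD cohort.

The sampling rate of the original recordings is not public; 500 Hz is the
configurable default (Nyquist comfortably above the 100 Hz analysis edge).

What the generator does **not** emulate: volume conduction from cortical
sources (no leadfield), non-stationarity, real eye/muscle artifact
morphology beyond stereotyped blinks, or inter-channel correlation of the
background. Passing tests therefore demonstrate that the pipeline recovers
the statistical structure it assumes, not that it would perform identically
on recorded EEG.

## Preprocessing

Fixed stage order: per-channel mean-centring → zero-phase 60 Hz notch
(IIR notch, −3 dB width 2 Hz, applied forward–backward; harmonics
optional) → average reference → amplitude-based artifact flagging
(|x| > 100 µV on any channel, padded by 100 ms; known-bad channels
excluded from the detector) → non-overlapping 1-s epochs, dropping every
epoch that touches a flag → bad-channel interpolation (unweighted mean of
the k = 4 nearest good channels in 3D) → first temporal difference, which
whitens the 1/f background in place of baseline normalization. The
amplitude criterion replaces the original visual artifact review and its
value is a configurable stand-in, not a reconstruction.

## Spectral topographic volumes

Each kept trial is linearly detrended, multiplied by one Hann window, and
reduced to periodogram power at 50 bin centres (1, 3, …, 99 Hz — the
"1–100 Hz in 2 Hz steps" wording is ambiguous between 1…99 and 2…100; the
odd grid is the default and configurable). The 64 × 50 values of a trial
are pooled and quantile-mapped onto Gamma(shape 1, scale 0.5) at plotting
positions (rank − ½)/n: scales become comparable across trials while the
within-trial ranks (the spectral pattern) are exactly preserved. Pooling
per trial over channels × bins is an interpretation; per-channel or
per-bin pooling would destroy either the topographic or the spectral
contrast. Shape–scale (mean 0.5) is assumed for the Gamma parameters.

Scalp maps use an azimuthal-equidistant projection of the 64 standard
10-05 electrode positions (MNE template, least-squares sphere centre,
vertex pole, anterior azimuth zero) onto the unit disc, scaled by the
largest electrode angle; each cell of the 20 × 20 grid (row 0 = anterior)
takes the value of its nearest electrode, ties broken by channel order,
with no head-circle masking. Stacking the 50 per-bin maps gives the
20 × 20 × 50 input volume.

## Network

Input (20, 20, 50, 1) → Conv3D(2, 3³, same, sigmoid) → AvgPool(2) →
Conv3D(3) → AvgPool → Conv3D(3) → AvgPool → BatchNorm → Flatten(189) →
Dropout(0.5) → ReLU → Dense(3, softmax). Average pooling uses ceiling
rounding (20→10→5→3, 50→25→13→7) and edge windows average only the
elements present; same-padding and ceil pooling are forced by the layer
shape chain even though never stated outright. Trainable parameters:
56 + 165 + 246 + 570 = 1,037, with 6 further batch-norm scale/offset
parameters (the headline count excludes them; both totals are exposed,
since the published per-layer rows sum to 1,043 while the text says
1,037). Batch norm is per feature over the batch (momentum 0.99,
ε = 10⁻³; inference uses running moments). The loss is class-weighted
categorical cross-entropy (the standard softmax partner) plus
L1 (10⁻⁴) · Σ|w| + L2 (10⁻²) · Σw² over the convolutional and dense
weight matrices. Forward and backward passes are explicit numpy code
(stencil convolutions via `scipy.ndimage.correlate`); analytic gradients
are verified against central finite differences in the test suite, which
is why the arithmetic defaults to float64 (float32 is available for long
training runs).

## Training

Random 75 / 12.5 / 12.5 % partition into training / validation / test.
The default is trial-level (trials of one subject may cross splits, as in
the original protocol — a subject-level option exists because trial-level
splitting permits within-subject leakage, which should be measured, not
silently "fixed"). One-time augmentation transforms three independent
random 33 % subsets of the training volumes: planar shift (offsets
uniform up to 20 % of the extent, zero fill), planar zoom (factor
0.88–1.12 about the grid centre), and elastic deformation (white
displacement noise smoothed by a Gaussian of SD 0.08 × extent, magnitude
uniform in [0, 1] cells); the frequency axis and map orientation are never
altered. Optimization is Adam (β₁ 0.9, β₂ 0.999, ε 10⁻⁷) under the
staircase schedule rate = r₀ · 0.96^⌊step/10000⌋. Steps are counted in
units of batch-size samples seen, so 75 epochs over 13,598 samples at
batch 25 is exactly 40,794 updates ending at 8.49 × 10⁻⁵ — the published
iteration count implies this carry-over convention rather than
ceil-per-epoch counting. Early stopping uses a 10-epoch validation-loss
patience under a 100-epoch cap. Fine-tuning to a new cohort updates only
the dense softmax layer (2 × 10⁻⁵, ≤ 45 epochs, batch-norm frozen) and
returns the best-validation epoch, with the untouched model included as a
candidate so fine-tuning can never end worse on the selection metric.

**Scaled-down schedule.** The full protocol's 1e-4 initial rate needs
tens of thousands of Adam steps to move a sigmoid network — at desk scale
(≈ 25 subjects/class × 60 trials, about a thousand update steps) it leaves
the network at chance. The synthetic-study driver therefore runs a short
schedule (10–12 epochs) with a proportionally larger initial rate (2 × 10⁻³,
same staircase shape). `TrainConfig` keeps the full-scale defaults; the
driver's schedule is a problem-size choice, recorded here.

## Evaluation

Winner-take-all accuracy is reported both unweighted and balanced (mean of
per-class accuracies), because published figures mix the conventions. The
ROC is built directly from its threshold functions tp(t) = P(S > t | pos),
fp(t) = P(S > t | neg) at every distinct score; the trapezoidal area
equals the Mann–Whitney pairwise probability with ties counted ½ (the
strict inequality in the threshold definition leaves ties open; ½ is the
convention adopted), and the suite verifies the equality against an
exhaustive pairwise oracle. Published accuracy/AUC levels for the original
OpenNeuro/OSF cohorts are exposed only as flagged reference constants —
reproducing them requires those datasets and full-scale training.

## Grad-CAM localization

For a test volume and target class, each filter of a convolutional layer
(default: the deepest, layer 3; shallower layers available for the
ablation) is weighted by the spatial+frequency mean of the gradient of the
class's pre-softmax score (the loss is available as an alternative
scalar); the weighted sum of the feature maps is the saliency map. No
rectification is applied — signed maps are kept because the negative
direction is interpreted (evidence for the *other* cohorts). Maps are
upsampled trilinearly to 20 × 20 × 50 using the half-pixel convention
((g + ½)/r − ½): with a cumulative pooling factor of 4, native cell i
covers grid cells 4i…4i+3 (centre 4i + 1.5), and half-pixel registration
places it exactly there, whereas align-corners would stretch the map by up
to 1.5 cells — enough to displace a peak by an electrode. Each map is
z-scored over its voxels.

Two across-trial reductions are provided. `t_volume` is the literal
one-sample t against zero per voxel. `contrast_t_volume` is the
one-versus-all two-sample (pooled) t: target-cohort maps against the
superposed other cohorts. The pipeline localizes with the contrast,
because on synthetic data the one-sample t is dominated by voxels whose
saliency is *stable* rather than *discriminative* (class-independent map
structure with near-zero across-trial variance produces arbitrarily large
t), while the contrast cancels everything common to the cohorts. Voxels
with t above the conservative threshold 20 are mapped back to electrodes
through the grid assignment and reported per canonical band (δ/θ 1–8,
α 8–12, β 12–30, γ 30–100 Hz; bins belong to a band by their centre,
left-closed). Frequency profiles average t over a cluster's cells per bin,
with prominence-based peak detection (ties reported in ascending
frequency).

**Localization resolution.** Arg-max-level recovery of an injected
cluster is limited in several structural ways, measured on the synthetic
benchmark. Zero same-padding attenuates convolutional activations at the
map boundary, so evidence for a cluster hugging an edge (the occipital
set) peaks one electrode row inside it — a controlled probe that doubles
beta power at the injected occipitoparietal cells moves the class
saliency peak to the correct band but to the P3/P5 row. The deepest
layer's native cell is 4 grid cells wide, so peaks often sit on an
electrode adjacent to a small cluster (FC2 beside FC1). And because the
per-trial gamma normalization is rank-based over the pooled volume,
raising power at one region lowers every other cell's value in that
trial, which couples voxels and lets the across-cohort contrast peak
drift to low-frequency bins in some training replicates. Across five
training replicates the arg-max voxel lands inside the injected electrode
set *and* band in only a minority of runs, although the supra-threshold
clusters overlap the injected sets substantially and the frequency
profiles peak in the injected bands. Cluster-level and band-profile
summaries are therefore the recommended reading of the maps; the
benchmark reports the strict arg-max criterion as measured.

**Known divergence (layer ablation).** On the synthetic benchmark,
localization specificity — the fraction of supra-threshold voxels inside
the injected region — is *higher* at layer 1 than at layer 3, under both
the contrast and the one-sample formulation. The injected evidence is
low-level band power, fully visible at input resolution, and a layer-3 map
upsampled from 5 × 5 × 13 spreads any supra-threshold native cell over
4 × 4 × 4 voxels, most of which fall outside a small cluster like the
four-electrode motor set. A voxel-fraction specificity measure therefore
structurally favours the shallow layer here; the opposite ordering
reported for the original recordings plausibly reflects class evidence
that only becomes linearly decodable deeper in the network. The benchmark
reports the measured ordering rather than forcing the expected one.

## Clinical association models

Median pre-normalization power over a cluster's electrodes × band bins ×
kept trials gives one feature per subject × cluster × state, rank-
normalized to a standard normal scale within cluster × state. Models are
Gaussian linear mixed models fitted by maximum likelihood with a
by-participant random intercept: the off-state models regress UPDRS motor
(off), disease duration, and LEDD on age + cluster power; the on-state
model regresses the on–off UPDRS change on on-state frontoparietal theta
power + age + off-state UPDRS + education. Inference on the power term is
by likelihood-ratio test, χ² = 2Δℓ clipped at zero, referred to χ²(df).
With one observation per participant the random-intercept variance is not
identifiable; the fit reports the boundary solution (variance 0, equal to
OLS under ML) and flags it instead of silently dropping the term.
Repeated-measures designs use the full mixed-model fit (statsmodels
MixedLM). Unadjusted p-values are primary, matching the original
reporting; a Benjamini–Hochberg column is appended as clearly supplementary
output.

Calibration is verified by simulation: under the null the LRT's type-I
error should sit at the nominal 5 %. The null simulation uses 100
subjects — with ~25 singleton subjects the χ²(1) reference is analytically
anticonservative (≈ 6.9 % rejection), a small-sample property of the LRT
worth knowing when reading the original p-values. Sign recovery of the
injected theta → ΔUPDRS effect is simulated at the configured effect size
(ρ = −0.6, n = 25, measurement noise SD 0.3 on the standardized gain).

## Problem sizes

The synthetic study driver defaults to 25 subjects per class, 60 s of
usable recording per session (≈ 3,800 kept trials after rejection), an
10-epoch training schedule, float32 training arithmetic, and Grad-CAM over
all test trials; the localization-recovery benchmark repeats the
stochastic analysis (partition, augmentation, initialization, dropout,
training) five times on one simulated cohort. Statistical calibration uses
1,000 null replicates and 100 sign-recovery replicates. These sizes are
the package's defaults for a complete run on a single CPU core; all of
them are configurable upward.

## Known limitations

* Trial-level partitioning (the protocol default) allows trials of one
  subject on both sides of the split; accuracy under it overstates
  subject-level generalization. The subject-level mode quantifies this.
* The synthetic background is spatially white; real EEG's volume
  conduction would smear both the classifier's evidence and the Grad-CAM
  localization.
* The Grad-CAM arg-max is only defined up to the deepest layer's native
  resolution (4 grid cells ≈ one electrode spacing); peaks can sit on an
  electrode adjacent to a small injected cluster.
* `simulate_null_lrt` covers the Gaussian linear boundary case; calibration
  of the mixed-model path with repeated measures is exercised only at
  small scale in the unit tests.
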