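# Methods

`cdti` implements a complete, self-contained workflow for studying how far a
cardiac diffusion-tensor acquisition can be shortened: simulate short-axis
left-ventricular (LV) diffusion-weighted datasets with known microstructure,
fit diffusion tensors by linear least squares (LLS) from the full acquisition
and from breath-hold-reduced subsets, train a U-Net to predict the full-data
tensors from the reduced data, derive the cardiac parameter maps, and compare
every reduced-data method against the full-data reference.

## Signal model and phantom

Diffusion attenuation follows the monoexponential tensor model
`S = S0 exp(-b g'Dg)` with `b` in s/mm^2 and `D` a symmetric positive-definite
rank-2 tensor (stored internally in 1e-3 mm^2/s, the scale on which mean
diffusivity is conventionally printed).

The phantom is an annulus standing in for the mid-ventricular LV myocardium
on a 2.8 x 2.8 mm grid: the wall spans endocardial radius 21 mm to epicardial
radius 33 mm and is divided into three equally wide transmural regions
(endo/meso/epi). Microstructure:

* **Helix angle (HA).** The primary eigenvector is the circumferential
  direction rotated toward the longitudinal axis by an angle that ramps
  linearly in transmural depth, +60 deg at the endocardium to -60 deg at the
  epicardium by default (10 deg/mm across the 12 mm wall).
* **Sheetlet angle (E2A).** The secondary eigenvector sits in the
  cross-myocyte plane at a fixed angle (default 60 deg, a systole-like value)
  from the wall-tangential reference direction.
* **Eigenvalues.** Defaults (1.8, 0.8, 0.6) x 1e-3 mm^2/s, giving
  MD = 1.067e-3 mm^2/s and FA = 0.54.
* **Mesocardial FA band.** In the middle third the second and third
  eigenvalues are spread symmetrically about their mean so that FA rises by a
  configurable fraction (default 0.15) at exactly unchanged MD; the required
  spread has a closed form and the generator rejects configurations whose
  spread would drive the third eigenvalue non-positive.
* **Infarct.** An optional transmural angular sector scales all three
  eigenvalues by `md_scale` (default 1.27): MD up, FA unchanged.

The acquisition protocol emulates a breath-hold exam: 12 breath-holds, each
holding one minimally weighted image (b0 = 0 by default) plus one
six-direction set, ten sets at b = 600 s/mm^2 and two at b = 150 s/mm^2
(giving 12 b0, 10 b600 and 2 b150 repetitions in total). The six directions
default to the dual-gradient scheme {(1,0,1),(-1,0,1),(0,1,1),(0,1,-1),
(1,1,0),(-1,1,0)}/sqrt(2). Noise is Rician: the magnitude of
(S + N(0, sigma), N(0, sigma)) with sigma = S0/SNR; the background contains
pure Rayleigh noise. Optional respiratory motion applies one in-plane
translation per breath-hold (N(0, motion_sigma_px), cubic-spline resampling)
before the noise. Motion defaults to zero; registration is exercised and
tested separately so that fitting results are not confounded by residual
interpolation error.

What the phantom does **not** emulate: real anatomy (papillary muscles, RV),
through-plane motion, cardiac-phase dependence, field-strength-specific
artifacts, and clinical noise heterogeneity. Passing tests therefore show
correctness and direction of effects under controlled conditions, not
clinical performance.

## Breath-hold reduction

Reduced datasets take the first breath-holds in acquisition order:

* `5BH`: 4 x (b0 + b600 set) + 1 b150 set = 34 images,
* `3BH`: 2 x (b0 + b600 set) + 1 b150 set = 20 images,
* `1BH`: 1 x (b0 + b600 set) = 7 images.

The b150 breath-hold contributes only its six diffusion-weighted images, so
the stated compositions (e.g. "four repetitions of b0 and b600 and one of
b150") hold exactly. An image flagged as corrupted (flags are explicit
inputs; quality control is manual) is replaced by its counterpart in the next
breath-hold of the same kind.

## Tensor fitting

The model is linearized by taking logs; each acquired image contributes one
row `[1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]` against
the unknowns `[ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]`. The system is solved
per voxel by QR factorization, unweighted, with no positivity constraint and
no noise suppression. Non-positive magnitudes are clamped to 1e-6 times the
median in-mask b0 signal before the log and the voxel flagged; a voxel with
all signals clamped gets a zero tensor and a failure flag. A rank check
(rank 7 required) rejects under-determined protocols with a named cause.

## Parameter maps

Per-voxel eigendecomposition (descending eigenvalues) with sign
disambiguation against the local wall frame: E1 is flipped so its
circumferential component is non-negative, E2 so the triad is right-handed.
The local frame puts the radial direction in-plane from the LV center
(cavity centroid for real masks, configured center for phantoms),
longitudinal along the slice normal, circumferential = longitudinal x radial.

* FA = sqrt(3/2) ||lambda - MD|| / ||lambda||, MD = mean(lambda). Negative
  eigenvalues are tolerated (FA may exceed 1 and is reported as-is).
* HA = atan2(longitudinal, circumferential component) of E1's tangential
  projection, folded to [-90, 90); undefined (NaN, flagged) for purely radial
  E1.
* E2A = signed angle in the cross-myocyte plane between E2 and
  t = normalize(E1 x radial), positive toward the radial direction, folded to
  [-90, 90); |E2A| is also reported.

Transmural HA profiles run from the center through every epicardial border
voxel, sampling HA by nearest-neighbor lookup at 0.5-px steps (interpolating
angles across the +/-90 fold would corrupt them). Per profile (>= 3 samples):
least-squares slope of HA vs distance (deg/mm), sample IQR, and |first -
last| range. Subject summaries: mean of absolute slopes (median available as
an option; the aggregation is not uniquely determined by convention), median
IQR, median range. On the default ramp the recovered mean gradient is ~2-3%
below the prescribed 10 deg/mm because discrete nearest-neighbor sampling
slightly stretches the sampled wall.

## U-Net tensor prediction

Inputs are repetition-averaged stacks — 13 channels (1 b0 + 6 b600 + 6 b150)
for 5BH/3BH, 7 channels for 1BH — jointly normalized to [0, 1] by the in-mask
maximum, background zeroed. Targets are the six components of the *reference*
(full-data LLS) tensors divided by a fixed factor of 500 after expressing
them in 1e-5 mm^2/s. On that scale a typical myocardial diagonal maps to
~0.21, so the factor indeed confines values to [-1, 1]; the unit is
configurable.

Architecture: per encoder level two (3x3 convolution -> batch norm -> leaky
ReLU 0.01) blocks then 2x2 max-pool; a two-block bottleneck; per decoder
level a stride-2 up-convolution concatenated with the matching encoder
features, batch norm + leaky ReLU, then two convolution blocks; final 1x1
convolution, linear. Filters double per level. Training: L1 loss, Adam
(lr 1e-4, beta1 0.9, beta2 0.999), batch size 8; weights are checkpointed
only when the validation loss improves, and the model ends at the best
checkpoint.

By default the L1 loss runs over myocardial pixels only
(`UNetConfig.mask_loss`). With an L1 loss the ~93% background pixels — whose
inputs and targets are both zero by the normalization contract — contribute
full-magnitude sign gradients on near-zero residuals; under a short
optimization budget that swamps the in-mask regression signal and leaves the
predicted eigenvalue spectrum too isotropic (inflated sheetlet-angle errors).
Restricting the loss to the heart concentrates every optimizer step on the
quantity the maps are computed from; predictions are zeroed outside the mask
at inference either way. An all-pixel loss remains available as an option.

The network is implemented directly on NumPy arrays (im2col + GEMM
convolutions with hand-written backward passes, verified against finite
differences), which makes training bit-reproducible for a fixed seed on one
CPU. Two scales exist:

* **clinical-scale** (constructible, not exercised by the tests): 6 levels,
  128 x 128 inputs, 500 epochs;
* **desk-scale** (the tested default): 3 levels, 16 top-level filters,
  64 x 64 phantoms, 200 training / 30 validation / 20 test subjects,
  50 epochs. These sizes keep a full study at ~10 minutes on one CPU.

The output head is initialized at small scale (std 0.01): with sub-unit
regression targets and a short optimization budget, starting near zero
output spends the optimizer on in-mask structure rather than on unwinding
large random initial outputs. Batch-norm statistics are frozen at inference;
kernel size 3x3 and stride-2 2x2 up-convolutions are standard choices.

## Evaluation

Pixel-wise errors against the reference maps: mean absolute error for FA and
MD; mean absolute *angular* error for HA and E2A with folding at +/-90 deg
(`d = min(|delta| mod 180, 180 - |delta| mod 180)`). Subject-level agreement:
median of test-minus-reference differences with empirical 5/95% quantiles and
a seeded percentile-bootstrap 95% CI of the median (10,000 resamples by
default); bias is "significant" when 0 falls outside the CI. Classical
mean +/- 1.96 SD limits are available as a secondary output. Scan quality is
the mean Dice overlap of the mask displaced by each image's residual
(true - estimated, rounded) shift; per-scan errors can be regressed on it.
Group comparisons dispatch Wilcoxon signed-rank (paired), rank-sum
(unpaired) or Kruskal-Wallis with pairwise follow-ups (unadjusted p by
default, Bonferroni optional; no multiple-testing correction is applied by
default). All tests are two-sided at alpha = 0.05.

## The full experiment

`experiment.run_study` simulates a cohort with randomized microstructure
(HA endpoints U(50,70)/U(-70,-50) deg, eigenvalues jittered ~+/-10% within
feasibility of the FA boost, wall radii 18-24 mm endo + 10-14 mm thickness,
E2A U(40,70) deg, SNR U(20,30), infarcts in half the subjects with md_scale
U(1.2,1.4) over a 60-120 deg sector), stratifies train/validation/test
splits on infarct presence by seeded largest-remainder allocation, computes
reference fits, trains one U-Net per reduction scheme on (reduced input,
reference tensor) pairs, and evaluates each test subject with both LLS and
the U-Net. All randomness flows from one master seed through named
substreams.

## Numerical and design notes

* Registration: multiresolution phase cross-correlation (integer estimates
  on a 2x pyramid, subpixel refinement at 0.1 px by default), cubic-spline
  resampling with zero padding; flat images get zero shift.
* Averaged channels are ordered b0, then the six b600 directions, then the
  six b150 directions, with directions in lexicographic order so the layout
  is independent of acquisition order.
* Eigen-degenerate (isotropic) tensors accept any orthonormal triad; FA = 0
  downstream.
* The phantom's angular statistics assume isotropic in-plane spacing;
  profiles reject anisotropic spacing explicitly.
* Max-pool gradients are split equally over tied maxima (ties are measure-
  zero for noisy inputs).

## Known limitations

* The mesocardial FA band at the default boost (0.15) and SNR 25 remains
  statistically detectable in reduced-data LLS maps: regional medians over
  ~90 voxels have a standard error of ~0.011 against a ~0.077 median gap, at
  any reasonable unit of analysis (voxels or angular sectors). The loss of
  band significance reported on clinical cohorts arises from clinical noise
  levels and inter-subject heterogeneity that the phantom deliberately does
  not model; the corresponding check is expected to fail under these
  synthetic conditions and is kept as an honest negative.
* The desk-scale U-Net is trained for 1250 optimizer steps; it demonstrates
  the direction of the method's advantages at one breath-hold, not the
  ceiling of a clinically trained model.
* Single 2D slice throughout; tensors are 3D but geometry is not.
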