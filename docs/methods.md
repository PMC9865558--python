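# Methods

## The color observation model

A camera channel's response to a surface under an illuminant is the
wavelength integral of sensitivity × illuminant × reflectance,

    o_j = ∫ c_j(λ) l(λ) r(λ) dλ .

All spectra live on one uniform wavelength grid (nm); the integral is
discretized with the rectangle rule, and the grid step Δλ is folded into
the per-pixel feature matrix `A = Cᵀ R Q` so that the discrete identity

    o = A x   (image under the mixed illuminant l = Q x)

holds *exactly* in floating point — rendering an image from precomputed
`A` and simulating the observation under the accumulated SPD give the
same numbers to round-off. The test suite asserts this equivalence to
1e-10 relative error over random scenes; it is the load-bearing property
of the whole approach, since it means one capture per sub-light suffices
for any illuminant mixture.

Working bands: 400–830 nm (visible, 5 nm step, 87 samples) and
400–1000 nm (extended to NIR, 121 samples). Resampling between grids is
linear interpolation; wavelengths outside a source's measured band get
zero intensity rather than an extrapolation, since physical SPDs vanish
outside their band.

Lighting weights are allowed to be negative by default: the "illuminant"
is then interpretable only as a post-capture linear combination of
sub-light images, not a physical lamp. Reconstructed SPDs flag negative
lobes (`ReconstructedSPD.has_negative_lobes`).

## Sub-lights, camera, reference illuminant

- **Simulated sub-lights**: 24 Gaussians, unit peak height, peaks
  412–987 nm at 25 nm spacing, FWHM 40 nm
  (σ = FWHM / (2√(2 ln 2)) ≈ 16.99 nm). A second peak table (405–780 nm)
  mirrors a measured 24-LED visible-band bank; Gaussian stand-ins can be
  generated at those peaks, and any measured SPDs can be supplied as CSV.
- **Camera**: a synthetic RGB quantum-efficiency model — three Gaussians
  peaking at 600/540/460 nm (σ 38 nm), optionally with an identical flat
  NIR tail on all channels beyond 830 nm to emulate sensors whose
  channels become indistinct in the NIR (NIR then carries no chromatic
  information). Measured sensitivities can be supplied as CSV.
- **Reference illuminant**: the CIE D65 relative SPD, packaged at its
  standard 10 nm values (380–830 nm, normalized to 100 at 560 nm) and
  linearly interpolated to the working grid at load; zero outside the
  tabulated band. The least-squares mixture `x_approx = Q⁺ q_D65`
  (Moore–Penrose pseudo-inverse, minimum-norm solution) defines the
  frozen-lighting baseline; its residual concentrates in the wavelength
  bands the sub-lights do not cover.

## Synthetic scenes

The generator emulates the structure of annotated oral/dental spectral
image databases without their data: a scene is an H×W grid of pixels
with full reflectance spectra in [0, 1] and an integer class mask
(−1 = unlabeled). Classes share one smooth baseline (a sigmoidal rise
from ≈0.35 to ≈0.65, typical of bright hard tissue) and differ by one
Gaussian bump each (default amplitude ±0.12, width σ = 12 nm) placed in
disjoint slots of a configurable band range, with a small seeded jitter.
Pixels add iid Gaussian reflectance noise (default sd 0.02, a plausible
per-pixel noise for laboratory reflectance imaging) and are clipped to
[0, 1]. Default task scale: 6 classes (one bump-free "healthy" baseline
class + 5 bumped classes), 48×48 scenes in 8×8 tiles.

What this does *not* model: spatial texture within a class, smooth
illumination gradients, specular highlights, class-boundary mixing,
radiometric calibration, photon noise, exposure/distance effects.
Passing tests therefore show the optimizers recover *spectral* structure
under idealized spatial statistics; they do not certify performance on
real tissue images.

Patches: one sample per labeled pixel whose p×p window (p odd; 1 or 5 in
practice) lies fully inside the image — windows crossing the border are
discarded rather than padded, and patches straddling class boundaries
are kept (the label is the central pixel's class only). Labels are
{−1, +1} for the SVM view and {0, 1}/one-hot for the network view of the
same dataset. Cross-validation folds are stratified by label and
deterministic given a seed.

## Alternating SVM optimization

The decision value `wᵀ A x + b` is bilinear in (w, x), so each block
subproblem is an ordinary linear SVM: the w-step fits on rendered
features `A_i x` ∈ ℝ^Nch, the x-step on projected features
`A_iᵀ w` ∈ ℝ^NL, whose "classifier weights" are the new lighting
weights. Design choices:

- **Soft margin.** The hard-margin constraint `y_i(wᵀA_i x + b) ≥ 1` is
  infeasible on noisy data; both subproblems use the hinge-loss soft
  margin with a shared penalty (default 1.0; hard margin recovered as
  the penalty → ∞). Subproblems are solved with libsvm
  (`sklearn.svm.SVC`, linear kernel, dual tolerance 1e-8); tests verify
  the x-step against an independent SLSQP solve of the dual QP.
- **Bias.** `b` is refit in whichever subproblem is being solved — it
  belongs to the margin problem at hand and is cheap.
- **Convergence.** The bilinear scale indeterminacy (w → αw, x → x/α)
  lets raw iterate norms slide without changing the classifier, and the
  solver noise floor is ~1e-3; convergence is therefore declared when
  the *normalized directions* of w and x both move < 1e-3 (euclidean)
  between sweeps, up to 50 sweeps.
- **Restarts.** 10 by default, x₀ ~ U[−1, 1]^NL, best trial kept by F1.
- **Ties.** A decision value of exactly 0 predicts +1, for determinism.

Because the x-step explicitly minimizes ‖x‖ subject to the margins, its
solution concentrates |x| on the sub-lights that carry class signal —
the mechanism behind the band-recovery results.

## The rendering-layer network

The lighting weights form the network's first layer: a batch of
p×p×Nch×NL A-blocks is contracted along the sub-light axis to a rendered
p×p×Nch image (`∂output/∂x_i` = the i-th sub-light block of the input),
so `x` and the classifier weights W train jointly by backpropagation.
The two forms — rendering inside the network, or the head applied to
pre-rendered images `A x` — are one computation and agree to float
associativity.

Architecture (per the searched grid): FCL head (1×1 pixels) = flatten →
n_layers ∈ {3,5,7} fully connected layers of n_units ∈ {10,15,20} with
activation ∈ {ReLU, none} and dropout p = 0.3 after each hidden FC
layer → 2-unit output; CNN head (5×5 patches) = two valid 3×3
convolutions with 10 filters, stride 1 (5→3→1 spatially, consuming the
patch exactly, no pooling or padding) → flatten → the remaining
n_layers − 2 FC layers → 2-unit output. Softmax lives in the
cross-entropy loss and in `predict_proba`; it is never applied twice.
Grid search enumerates 3×3×2 = 18 architectures per head and ranks by
cross-validated mean F1.

Numerical choices:

- **Standardization.** Rendered intensities carry a DC component much
  larger than the class contrast; feeding them raw kills the ReLUs and
  collapses training. A fixed per-channel affine standardization sits
  between the rendering layer and the head, calibrated once from the
  rendered training data under the initial lighting weights and then
  frozen. It holds no trainable parameters and, being affine, leaves
  end-to-end differentiability in x and the two-form equivalence intact.
- **Optimizer.** Adam (β = 0.9/0.999, ε = 1e-8), learning rate 1e-3,
  200 epochs, batch 64 by default — all config-exposed. Training is
  deterministic given the seed (one generator drives shuffling and
  dropout). Cross-entropy is log-sum-exp stabilized.
- **Initial lighting weights**: iid U[−1, 1] (default), iid U[0, 1],
  the D65 pseudo-inverse approximation, or all-ones.
- **Class imbalance**: none by default; inverse-frequency weighting is
  deliberately not applied.

All layers and gradients are hand-written NumPy; correctness is
established by central-finite-difference checks (≤1e-4 relative) on both
heads, which the test suite runs routinely.

A known property, visible in the tests: unlike the SVM x-step, gradient
training has no norm penalty on x, and scale can migrate freely between
x and the head weights. The *magnitude profile* of the learned x is
therefore unstable across folds and seeds (solutions differ per fold and
need not be locally optimal); the reproducible observable is the learned
update x − x₀, whose mass concentrates on the informative sub-lights.
Multiple restarts with different initializations remain advisable.

## Evaluation

- **Metrics**: F1 = 2TP/(2TP + FP + FN) of the target class (0 when the
  denominator vanishes), accuracy, and raw confusion counts; all model
  selection ranks by F1.
- **Cross-validation**: stratified k-fold (default 5); each fold stores
  its learned lighting weights so per-fold optimal SPDs `Q x` can be
  reconstructed (normalizations: none, unit peak, unit l2).
- **Mahalanobis analysis**: squared distance
  `(f − μ_c)ᵀ Σ_c⁻¹ (f − μ_c)` of every "rest" sample from the target
  class distribution, in the rendered-feature space (flattened patches;
  75 dimensions for 5×5 RGB). Σ_c is the mean-centered covariance with
  1/(N_c − 1) scaling plus a ridge (default 1e-6 · trace/N_d); the
  literal uncentered second-moment form and a square-rooted output are
  available behind flags for fidelity comparisons. Distances of held-out
  samples are computed against a training-set distribution. The target
  class needs comfortably more samples than feature dimensions for the
  covariance to mean anything — the packaged analysis uses a 40×40 scene
  (≈500+ target patches for 75 dimensions).
- **Lighting comparison**: per method and target class, CV F1/accuracy
  with trainable/optimized x versus x frozen at the D65 approximation,
  on identical folds and seeds, reported as paired per-fold differences.

## Problem sizes

The packaged experiments are deliberately small so everything re-runs on
one CPU: 24×24 scenes (576 pixels) for the classification studies, 40×40
for the distance analysis, 5-fold CV, a few hundred training epochs.
These sizes were chosen as the smallest at which the spectral-recovery
effects are unambiguous; they scale up linearly in pixels and epochs.

## Known limitations

- The NN lighting solutions are non-unique and fold-dependent (see
  above); only their direction of change is a stable read-out.
- The synthetic generator's idealizations (no texture, no specularity,
  iid noise) make the tasks easier than real tissue classification;
  absolute F1 values here say nothing about absolute performance on
  real data, only the *orderings* (optimized ≥ fixed illuminant) and
  recovery behaviors are meaningful.
- Radiometric effects (source distance, exposure, photon noise) are out
  of scope; A-matrices are treated as noiseless linear measurements.
- Kernel SVMs, multiclass segmentation heads, and 4-channel RGB-NIR
  cameras are not implemented.
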