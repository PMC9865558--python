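# illumopt

Light-source spectrum optimization for machine vision.

A scene's appearance to a camera depends on the illuminant: changing the
spectral power distribution (SPD) of the light changes which spectral
features of a surface end up in the camera's few channels. When the
working light is a mixture of `NL` elementary sources ("sub-lights", e.g.
LEDs) with spectra `Q = [q_1 … q_NL]` and mixing intensities
`x = (x_1 … x_NL)ᵀ`, a pixel's channel response factors as

```
o = Cᵀ R Q x = A x,        A = Cᵀ R Q ∈ ℝ^{Nch×NL}
```

with `C` the camera's spectral sensitivities and `R = diag(r)` the pixel
reflectance. `A` can be captured once (one shot per sub-light); any
illuminant mixture is then *rendered* as `A x` without re-photographing —
and, crucially, the rendering is linear in `x`, so `x` can be optimized
for a downstream recognition task.

This package implements that idea for one-vs-rest classification of
spectrally similar tissue classes (healthy enamel vs. lesion-like
classes), with two optimizers of the lighting weights:

- **Alternating SVM** (`AlternatingSVMClassifier`): alternately solve a
  linear soft-margin SVM for the classifier weights `w` given `x`
  (features `A_i x`), and the *equivalent* SVM for `x` given `w`
  (features `A_iᵀ w`), with random restarts.
- **Rendering-layer network** (`NeuralLightingClassifier`): `x` is the
  first, trainable layer of a neural network (FCL head for 1×1 pixels, a
  small CNN for 5×5 patches); `x` and the classifier weights are updated
  jointly by backpropagation on the softmax cross-entropy. The layers
  and gradients are implemented directly in NumPy.

Because real annotated spectral-image databases are large external
downloads, the package ships a first-class synthetic generator
(`illumopt.synthetic`): labeled reflectance cubes whose classes share a
smooth baseline and differ only in narrow wavelength bands — the regime
where illuminant design pays off. Evaluation tooling covers stratified
cross-validation, F1/accuracy, optimal-SPD reconstruction `Q x`,
fixed-illuminant (CIE D65) baselines, and Mahalanobis interclass-distance
analysis of the rendered feature space.

## Worked example

Two classes whose reflectances are identical except inside 620–670 nm,
observed through a synthetic RGB camera under 24 simulated Gaussian
sub-lights (peaks 412–987 nm, FWHM 40 nm):

```python
import numpy as np
import illumopt as il
from illumopt.alternating import AlternatingSVMClassifier

grid = il.make_grid(400, 1000, 5)
sublights = il.simulated_sublights(grid)
camera = il.synthetic_rgb_camera(grid)

models = il.make_class_spectra(2, grid, seed=0, band_range=(620, 670))
scene = il.generate_scene(models, 24, 24,
                          il.block_layout(24, 24, 2, tile=6), seed=1)
ds = il.make_patch_dataset(scene, camera, sublights, patch_size=1,
                           target_class=1, k_folds=5, seed=0)

x_d65 = il.approximate_illuminant(sublights, il.load_d65(grid)).x_approx
for name, method, kw in [
    ("alternating SVM", "alt", {"n_trials": 5}),
    ("rendering-layer NN", "fcl", {"epochs": 400}),
    ("SVM, D65 frozen", "alt", {"optimize_lighting": False,
                                "fixed_x": x_d65}),
]:
    res = il.cross_validate(method, ds, 5, seed=0, **kw)
    print(f"{name:20s} mean CV F1 = {np.mean([r.f1 for r in res]):.3f}")

clf = AlternatingSVMClassifier(n_trials=5, random_state=0).fit(ds.A, ds.y)
top = np.argsort(-np.abs(clf.x_))[:3]
print("top-weighted sub-lights (peak nm):", sublights.peak_nm[top])
```

Output:

```
alternating SVM      mean CV F1 = 1.000
rendering-layer NN   mean CV F1 = 1.000
SVM, D65 frozen      mean CV F1 = 0.990
top-weighted sub-lights (peak nm): [662. 637. 687.]
```

The optimizer puts its lighting weight on exactly the sub-lights whose
Gaussians cover the discriminative band (637/662/687 nm), and
cross-validated F1 under the optimized light meets or beats the frozen
D65 reference in every fold — the light itself has been made part of the
classifier.

The same pipeline is scriptable from the shell:

```sh
illumopt simulate-data --classes 2 --out scratch/scene
illumopt train-alt --scene scratch/scene --out scratch/alt
illumopt train-nn  --scene scratch/scene --model cnn --out scratch/cnn
```

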