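# Methods

This note documents the models, numerical conventions and design choices
behind `bmelseg`, and what the synthetic studies do and do not establish
about real data.

## Problem model

A subject contributes two co-registered 3D volumes: a fluid-sensitive target
sequence in which bone-marrow-edema-like lesions (BMEL) are hyperintense, and
a conditioning sequence in which the same lesions are nearly isointense.
Bone masks are inputs (in clinical practice they come from a separate
segmenter; the phantom generates them). Two assumptions carry the whole
framework: (1) lesions occur only inside bone marrow, so anomalies outside
bone are artifacts by definition; (2) a generative model trained exclusively
on healthy images synthesizes healthy anatomy even when conditioned on a
lesioned subject's data, so the positive part of (real − synthesized) is a
lesion signal. The positive part, not the absolute difference, is used
because lesions are hyperintense in the target sequence; negative residuals
are synthesis error, not pathology.

## Phantom generator

The phantom is first-class, tested code, not a fixture. Each study is a
deterministic function of (config, seed):

* **Bone**: two perturbed ellipsoids (femur/tibia analogues) whose volumes
  are sized from a drawn bone fraction (default range 0.10–0.18 of the grid);
  a smooth random field roughens the boundary. Default grid 16×64×64
  (slices × rows × cols), spacing 3.0×0.4×0.4 mm — thick sagittal slices,
  fine in-plane resolution.
* **Lesions**: 1–3 ellipsoids per study (radius 3.5–6 in-plane voxels,
  flattened through-slice), blurred with an anisotropic Gaussian
  (σ = 1.2 in-plane, 0.3·σ through-slice, since diffuse boundaries are an
  in-plane feature at this slice thickness), then passed through a
  plateau-preserving clamp (min(1, 1.6·field)) so lesion cores carry the full
  configured contrast while boundaries stay diffuse. Ground truth is the
  half-maximum level set; the field is truncated below 0.05 to give it
  compact support and is multiplied by the bone mask, so truth ⊆ bone by
  construction.
* **Intensities**: conditioning ≈ 0.35 background + 0.20·bone +
  0.02·lesion-field (near-isointense); target ≈ 0.45 background − 0.25·bone
  (dark, fat-suppressed marrow) + 0.5·lesion-field. Smooth texture fields and
  i.i.d. Gaussian noise (default sd 0.02) are added; a `healthy_target` copy
  shares the same noise so it equals the target exactly outside the lesion
  field's support. Per-sequence multiplicative scales drawn from (0.5, 2.0)
  emulate mixed scanner bit depths; the target and its healthy reference
  share one scale.
* **Raters** (default 2): each re-thresholds the smooth lesion field at
  0.5 + N(0, 0.08), randomly dilates/erodes by up to 1 voxel, and drops each
  lesion component with probability 0.1 — the three disagreement modes
  (threshold, extent, presence) seen between human annotators. All-zero
  jitter reproduces the ground truth exactly.

Lesion size/count distributions are free parameters chosen for plausibility
at this grid scale; no cohort statistics exist to calibrate them.

**What the phantom does not emulate**: anatomical detail (cartilage,
menisci, trabecular texture), MRI physics (bias fields, partial-volume
effects, sequence-specific artifacts), registration error, and pathology
other than marrow lesions. Passing tests therefore show the *framework* —
preprocessing, task construction, training dynamics, anomaly postprocessing,
thresholding, and scoring — behaves as specified; they do not certify
clinical performance, which depends on generator quality on real anatomy.

## Preprocessing

Per volume (all slices jointly): divide by the maximum absolute intensity;
clip to the 0.001/0.999 empirical quantiles; affinely map the post-clip
[min, max] to [−1, 1] (the tanh output range of the generators); optionally
center-crop in-plane with floor offsets on odd remainders. Quantiles are
outward-rounded order statistics (`lower` for the low tail, `higher` for the
high tail) rather than interpolated values: the clip bounds are then actual
voxel values, and the full pipeline is exactly idempotent on its own output,
which interpolated quantiles violate at the ~1e−5 level on continuous data.
The pseudo-healthy reference volume is transformed with the parameters
fitted on its real target volume, so "healthy equals target outside lesions"
survives standardisation — the oracle backend depends on this.

## Generative backends

Both trainable backends run on a small NumPy layer library written for this
package (im2col convolutions, manual backpropagation, Adam); at desk scale
(64×64 slices, 16–32 channels) this trains in seconds per hundred steps on
one CPU. Float32 is used throughout the networks: training is
memory-bandwidth-bound and the losses tolerate it.

* **cGAN**: two-level U-Net generator (skip connection, tanh head) and a
  three-convolution patch discriminator. The generator minimises the
  non-saturating adversarial loss −E[log D(x̂,c)] plus λ·E‖x − x̂‖₁ with
  λ = 100 (the standard Pix2Pix weight; no value is otherwise prescribed);
  the discriminator minimises binary cross-entropy. Adam with β₁ = 0.5,
  learning rate 5e−4, desk batch 4. The latent z is implicit (no explicit
  noise input), standard Pix2Pix practice. A `full_scale_preset` keeps the
  originally reported configuration (batch 36, zero initialisation); note all-zero
  initialisation leaves a conv net at a symmetric saddle, so the default is
  He initialisation and "zeros" is only a documented option.
* **Conditional diffusion**: the same U-Net, no output activation, taking
  concat(x_t, c) plus a sinusoidal timestep embedding projected to a
  per-channel bias. Quadratic schedule β_t = (√β₁ + (t−1)/(T−1)·(√β_T −
  √β₁))², β₁ = 1e−4, β_T = 0.02; desk default T = 100 (preset: 1000).
  Training minimises E‖ε − ε_θ(x_t, c, t)‖²; sampling is ancestral with the
  x₀-parameterised posterior mean, no noise injected at t = 1, output clamped
  to [−1, 1], deterministic given the sampling seed. With a noise model that
  predicts the exact forward noise, the final reverse step recovers x₀ to
  machine precision — the mechanics test exploits this closed form.
* **Oracle**: a lookup from (study, slice, task) to the preprocessed healthy
  target slice, rendered through the same task masking as the real target.
  It is the perfect-generator reference that isolates postprocessing from
  synthesis quality.

## Thresholding and scoring

Anomaly maps are bone-masked, then binarized at a single shared τ (no
per-volume normalisation by default; a volume-wise max-normalisation flag is
easy to add upstream of the sweep if maps are heteroscedastic across
subjects). τ is chosen per fold of a three-volume-fold cross-validation:
51 evenly spaced candidates spanning the training folds' pooled anomaly
range, scored by mean DICE (volumes averaged per rater, then raters
averaged), ties broken toward the smallest τ — the more sensitive
segmentation. Folds are assigned by volume, never by slice, to avoid
leakage; the assignment is a seeded permutation.

DICE uses smoothing ε = 1e−6 by default (ε is reported in every output; no
canonical value exists). With ε = 0 an empty-vs-empty comparison is
undefined: 2D slice averaging then either skips the slice or counts it as 1,
per an explicit policy; 3D DICE is computed from total counts and is immune
to empty slices. Binarization uses strict inequality (value > τ), so a zero
threshold on an all-zero map yields an empty mask.

Intra-rater reliability compares one rater's repeat annotation sets;
inter-rater compares different raters' first sets. Each row reports 3D,
2D all-slices, and 2D lesion-slices DICE averaged over common volumes.

## Numerical and degenerate-input conventions

* Constant volumes: quantile clip is the identity; rescale raises (degenerate
  range).
* Grids smaller than 8 voxels in any dimension are rejected by the phantom.
* Training sets reject any study with a nonempty lesion mask — healthy-only
  training is the method's premise, so it is enforced, not assumed.
* Lesioned phantom studies are guaranteed ≥ 1 truth voxel (bounded reseeded
  retries in the rare case blurring erases a minimal lesion).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-study and per-rater seeds are drawn once
  from the master seed, so datasets are reproducible and each study is
  independently regenerable.

## Problem sizes used in tests

Unit tests run on 8×32×32 grids; framework-level checks use the default
16×64×64 phantom: six lesioned volumes for threshold cross-validation, three
healthy studies (two train, one held out) for the 200-step cGAN runs, and
200-step diffusion runs at T = 50 on the small grid. These sizes are the
package's desk-scale operating point; the configuration presets carry the
full-scale values for users with the data and hardware to use them.

## Known limitations

* The phantom's simplicity means generator quality on it does not predict
  clinical DICE; only the oracle-backend results isolate the framework's own
  ceiling.
* No connected-component or morphological cleanup of segmentations is
  applied (none is part of the method).
* Surface-distance metrics (Hausdorff, ASSD) and volumetric error are out of
  scope.
* The diffusion backend at full scale (T = 1000, 256×256) is impractical on
  a single CPU; presets are provided but untested at that scale here.
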