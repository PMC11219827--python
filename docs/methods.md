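# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the desk-scale problem sizes the test suite
uses. Notation: spectra are intensity vectors `S(ν_i)` on a uniform
wavenumber grid of 619 samples spanning 500–1800 cm⁻¹
(Δν = 1300/618 ≈ 2.103 cm⁻¹ per pixel; "pixel" always means one grid
step). Labels are binary with cancer/precancer as the positive class.

## Preprocessing

Raw spectra are conditioned in a fixed order: (1) 5-point box-car
smoothing with truncated windows at the edges, so the operator is a true
local mean everywhere; (2) fluorescence-background removal by iterative
modified polynomial fitting: a fifth-order polynomial is fitted to the
spectrum, samples above the fit are replaced by the fitted values, and
the fit is repeated until it changes by less than `poly_tol = 1e-4`
(relative L2) or 500 iterations; the final fit is subtracted; (3)
normalization to unit trapezoidal area over 500–1800 cm⁻¹.

Numerical notes. The polynomial basis is evaluated on the grid mapped to
[−1, 1] and the fixed design matrix is pseudo-inverted once, so each
iteration is a single matrix product for an entire cohort. The iterative
clip-and-refit loop converges to (a polynomial near) the *lower envelope*
of the spectrum. Two consequences are documented limitations: on noisy
spectra the removed baseline sits at the noise floor rather than its
mean, and re-applying the operator is only approximately idempotent
(each application shaves the evolving envelope again; ~2% L2 change on
noiseless baseline-plus-peaks fixtures, more with a dense noise floor).
Peak apex heights over smooth baselines are recovered within 5%, which
is the property the classifier inputs rely on.

## Synthetic cohorts

The clinical dataset the pipeline targets (731 skin lesions: 340
cancerous/precancerous, 391 benign) is not public, so `ramandx.synthetic`
generates cohorts with its statistical structure:

* Eight shared Lorentzian bands at 855, 936, 1002, 1271, 1302, 1445,
  1655, 1745 cm⁻¹ (FWHM 20 cm⁻¹; Lorentzian is the conventional Raman
  line shape). Relative apex amplitudes 0.50, 0.45, 0.60, 0.55, 0.60,
  1.00, 0.85, 0.25 put the CH₂-bending band (1445) and amide-I band
  (1655) strongest, as in skin.
* Class contrast is purely multiplicative on band intensities: the
  cancer class has the 1445 and 1655 cm⁻¹ bands raised 15% and the
  1002 cm⁻¹ phenylalanine band lowered 10%. Both classes share every
  band; only intensities differ.
* Per-lesion, per-band lognormal amplitude jitter (σ = 0.10), a global
  lognormal intensity factor (σ = 0.30, removed by area normalization),
  a strictly positive random cubic fluorescence baseline with mean
  amplitude 5× the mean Raman signal, and additive Gaussian noise with
  σ = 8% of the lesion's peak Raman intensity.

The free dials (lesion variability and noise) were calibrated once so
that a linear classifier trained on a 512-case stratified training set
reaches test AUC ≈ 0.88 — the operating point the pipeline is designed
around — with the variability budget deliberately tilted toward
measurement noise ("moderate-noise" cohorts). That tilt matters twice:
noise-injection augmentation only has something to teach when the test
spectra are themselves noisy, and the failure of unregularized logistic
regression at p > n (below) requires enough high-dimensional variability
that interpolating fits do not generalize. With the default contrasts
removed (`class_effect ≡ 1`) the same cohorts are verified to be
unlearnable (linear test AUC 0.40–0.60).

What the generator does **not** emulate: multi-lesion patients, lesion
subtypes, instrument drift, cosmic rays, detector saturation, or any
biophysically derived constituent spectra. Passing tests therefore show
that the pipeline behaves correctly on data with the assumed *structure*,
not that the clinical AUC values are reproduced — those depend on the
private data and are out of reach by construction.

## Augmentation operators

Training sets only; validation and test sets are never augmented. With
`I_max` the global maximum intensity of the pre-augmentation training
set (computed once and reused, including for test-corruption grids):

* noise: `S′(ν_i) = S(ν_i) + N(ν_i)`, `N = 2(rand()−0.5)·k/100·I_max`
  (i.i.d. uniform per sample);
* shift: `S′(ν_i) = S(ν_{i±m}) + N(ν_i)`; vacated edge samples replicate
  the terminal value (keeps intensities in physical range, no zero
  cliffs);
* combination: `S′ = r·S₁ + (1−r)·S₂ + N`, `r ~ U(0,1)`, both spectra
  drawn from the *same* class — cross-class mixing is refused.

The default recipe is one 5% noise copy per spectrum, the six signed
shifts ±1, ±2, ±3 (each with 5% noise), one within-class combination per
training spectrum (with 5% noise), and 5000 GAN spectra per class:
512 originals expand to 14,608 (14,096 without the originals, 4,608
without the GAN, 4,096 without either). When a recipe requests fewer
combinations than training spectra they are allocated across classes by
largest remainder, so per-class counts always match the recipe
arithmetic.

## Conditional 1D-GAN

Generator: latent vector of length 4 (standard normal) in one channel
plus one-hot class channels, upsampled through five transposed-conv
stages with kernel/stride/padding (3,1,0), (7,4,1), (7,3,1), (7,4,1),
(5,2,1) — stage lengths 6, 25, 77, 309, 619 by `o = (i−1)s − 2p + k` —
batch-norm + ReLU after stages 1–4, linear output. Discriminator: the
spectrum plus a constant ±1 class channel through five conv stages
(5,2,1), (7,4,1), (7,3,1), (7,4,1), (6,1,0) — lengths 309, 77, 25, 6, 1
by `o = (i + 2p − k)/s + 1` — LeakyReLU (slope 0.2) after stages 1–4,
no batch norm (only the generator's normalization is specified; the
asymmetry is deliberate and conventional for DCGANs). Channel widths are
(8, 4, 2, 1) × `base_width` and 1 at the output; `base_width = 64` is
the full-scale model, smaller widths give desk-scale models with
identical stage lengths.

Training: non-saturating BCE adversarial loss, Adam with learning rate
2·10⁻⁴ and moment decays 0.5/0.999, mini-batch 256. Spectra are
standardized internally (per-wavenumber mean removed, global scale) and
de-standardized on synthesis; without this the generator spends most of
its budget learning the dominant mean shape. Each iteration draws one
fake batch that serves both the discriminator update (as a negative) and
the generator update (re-scored through the updated discriminator).
The discriminator additionally scores each real batch with deliberately
wrong class labels as a negative example (a matching-aware conditional
discriminator): without this term the label input carries no gradient
until fakes are otherwise perfect, and class conditioning never emerges
at desk-scale epoch budgets. The full-scale schedule is 25,000 epochs;
the package default is a desk-scale 500, and the test suite uses 150–300
epochs at `base_width` 2–4.

## 1D-CNN classifier

Input 1×619, then four stages of [conv(kernel 3, stride 1, 'same'
padding) → batch-norm → ReLU → average-pool(2, stride 2)] with 16, 32,
64, 128 kernels, then fully connected 256, fully connected 2, softmax —
21 layers under the convention that counts input, the 16 stage layers,
both fully connected layers, softmax and output. 'Same' padding keeps
conv stages length-preserving; each pool maps L to ⌊(L−2)/2⌋+1 (no pool
padding), so 619 → 309 → 154 → 77 → 38 and the flattened width is
38·128 = 4864. There is no nonlinearity between the two fully connected
layers — the enumeration above has none.

Training: Adam (0.9/0.999), initial learning rate 10⁻³ multiplied by 0.9
every 2 epochs (`lr(e) = 10⁻³·0.9^⌊e/2⌋`, e zero-based), mini-batch 256
for original-scale training sets and 1024 for augmented ones, partial
trailing batches dropped (512 cases at batch 256 ⇒ 2 iterations/epoch,
200-iteration budget over 100 epochs). Validation accuracy and
cross-entropy on the full validation set are evaluated every iteration;
training stops when validation accuracy has not exceeded its running
best for `early_stop_patience` iterations (default 50, the top of the
sensible 10–50 range). The final model keeps the last iteration's
weights; `restore_best=True` optionally rewinds. Inputs are standardized
with training-set statistics inside the model.

The CNN and GAN run on `ramandx.nn`, a small numpy layer engine with
hand-written backward passes (verified against central differences in
the test suite) and an Adam optimizer; there is no deep-learning
framework dependency. Float32 GEMM-based convolutions reach roughly
10 GFLOP/s on one CPU core, which sets the desk-scale budgets below.

## Chemometric comparators

All four expose a continuous score for ROC analysis and are fitted on
exactly the same split (and the same augmented training set) as the CNN:

* **PLS-DA** — PLS regression on a 0/1 response, 10 components (capped
  by rank); score = predicted response.
* **PC-LDA** — PCA retaining 95% variance, component count capped at
  min(n−2, p), then LDA; score = positive-class posterior.
* **SVM** — linear kernel, C = 1, on standardized features; hinge-loss
  dual fit (liblinear); score = signed decision value. The linear kernel
  is the deliberate choice: it reproduces the qualitative augmentation
  response of the reference pipeline, whereas an RBF machine starts near
  its ceiling on these cohorts and shows none.
* **LR** — *unregularized* logistic regression fitted by IRLS (GLM with
  binomial family, statsmodels), iteration cap 25, separation warnings
  recorded. The solver choice is essential: when features (619)
  outnumber cases (512) the classes are separable, the MLE does not
  exist, and the capped IRLS iterate scores held-out data near chance —
  the phenomenon the pipeline is designed to exhibit and then cure by
  augmentation. Gradient-descent fits (lbfgs and friends) are implicitly
  regularized and quietly generalize well, and any default penalty would
  hide the effect entirely.

## Evaluation harness

Each repetition r draws a stratified 70/10/20 split with seed
`base_seed + r`: per class, round-half-up(0.7·n_c) cases to training and
round-half-up(0.1·n_c) to validation, remainder to test — the only
rounding rule that partitions 340+391 into 512/73/146. The training
portion is optionally augmented (a fresh conditional GAN is trained on
that repetition's training set, so nothing leaks into validation or
test), every model is fitted on identical data, and ROC AUCs are
recorded for train/validation/test. AUC is computed as the trapezoidal
area under the empirical ROC, which equals the Mann–Whitney pair-ordering
probability with ties counted ½ (verified against brute-force pair
counting). Model failures are recorded as NaN cells without aborting the
harness. Arms run sequentially; repetitions are seeded independently, so
results are order-independent.

Robustness grids corrupt the original test set one axis at a time: noise
cells apply uniform noise at k% of the training `I_max`, shift cells
translate by m pixels (no noise), and the (0%, 0 px) cell is the
untouched test set. Corrupted spectra are deliberately **not**
re-normalized — the corruption models instrument degradation downstream
of preprocessing; `renormalize` would hide exactly the miscalibration
being probed.

Paired model comparison uses the two-sided Wilcoxon signed-rank test on
per-repetition AUC differences, zero differences dropped, exact null for
up to 25 informative pairs and the continuity-corrected normal
approximation above.

## Desk-scale problem sizes

The reference protocol (56 repetitions, 25,000 GAN epochs, 10,000 GAN
spectra) is a cluster-scale computation. The shipped test suite runs the
full pipeline at sizes chosen for a single CPU core:

* Stochastic end-to-end properties: the full 731-lesion cohort (the
  p > n logistic-regression failure requires the full 512-case training
  set), R = 4 repeated splits per arm, GAN at `base_width` 4 for 200
  epochs, 512 GAN spectra per class (training sets of 512 vs 5,632),
  CNN epoch budgets of 12 (original arm) and 4 (augmented arm), chosen
  so both arms see roughly matched iteration counts at their respective
  mini-batch sizes. The comparators' augmentation margins (+0.05 to
  +0.3) are large against the paired-split standard error at R = 4. The
  CNN's margin is not: in the reference protocol the CNN's gain comes
  almost entirely from the GAN-synthesized spectra, and with a
  desk-scale GAN (which captures class-conditional means but
  underrepresents within-class variance) the CNN's augmentation benefit
  shrinks to roughly the split-to-split noise level (±0.01–0.02). A
  strict "augmentation improves *every* model" assertion is therefore
  expected to be fragile in the CNN coordinate at this scale.
* GAN behavior tests: 100–200 toy spectra, `base_width` 4, 150–300
  epochs.
* Everything else (arithmetic, bookkeeping, formulas, I/O) runs at full
  fidelity — those quantities are exact and scale-free.

## Known limitations

* The GAN at desk scale learns the class-conditional mean shapes well
  (mean-spectrum correlation ≥ 0.97 at full cohort size) but
  underrepresents within-class variance; its augmentation value is
  correspondingly smaller than a full-scale run's.
* Early stopping on a 73-case validation set is noisy; per-repetition
  CNN AUCs fluctuate by ~0.02–0.03, which is why all directional claims
  are made on means over repetitions.
* The iterative polynomial baseline removal tracks noise floors (see
  above); spectra should be smoothed before it, as the default chain
  does.
* `stratified_split` requires at least 3 cases per class; degenerate
  single-class sets are rejected at the type level.
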