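# Methods

## Scope and shape of the package

The package couples a physics-based dual-energy projection simulator with
a learned projection-domain material decomposition. The learned model is
a paired image-to-image regression, so the public front end is a
scikit-learn style estimator (`DualHeadPix2Pix`, with `fit`/`predict`,
`get_params`/`set_params` and trailing-underscore fitted attributes);
the simulator, networks, losses, trainer and metrics remain importable
as plain modules underneath it.

Because the package targets plain CPU environments, the neural networks
run on a small reverse-mode autodiff engine written on NumPy
(`autodiff.py`, `nn.py`): strided conv / transposed conv via im2col,
batch normalization, dropout, logit-space binary cross-entropy through a
stable softplus, and Adam. Every primitive's gradient is verified
against central finite differences in the test suite.

## Forward model and phantoms

Phantoms are defined **directly in the detector plane** as per-pixel
path-length maps `t_m` (cm) for soft tissue, bone and iodine solution —
no ray tracing. Rotation over the 360 one-degree views is emulated
parametrically: each internal structure carries axial-plane coordinates
(x, y) and projects to lateral position `x·cosθ + y·sinθ`, which
reproduces the mirror symmetry of opposed views and a plausible
parallax, while making every view an exact function of
(subject seed, angle). The GAN operates purely in the projection domain,
so projective realism rather than tomographic consistency is what the
training data needs to supply.

Anatomy per subject: a cylindrical soft-tissue body (chord-length
thickness profile), evenly spaced ellipsoidal vertebrae with symmetric
rib arcs, and a recursively branching iodinated vessel tree plus a
cardiac blood pool. Structure randomness (tree growth, jitter) is drawn
from the subject seed only. Where bone or iodine displaces tissue the
soft-tissue map is reduced accordingly, so total thickness stays
physical.

Counts per energy bin follow Beer–Lambert,
`λ_b = N0_b · exp(−Σ_m μ_{m,b} t_m)`, with optional Poisson sampling.
The low threshold collects all counts, the high threshold only the
high-energy bin, so the threshold images satisfy
`counts_thr_low ≥ counts_thr_high` pixel-wise by construction.
Log projections use `P = −ln(max(counts, 1)/N0)`; the clamp to one count
avoids infinities under photon starvation.

Default attenuation values (1/cm, configurable, representative rather
than authoritative): soft (0.77, 0.25), bone (4.00, 0.60), iodine
solution (2.50, 1.80) for the (low, high) bins; fluence 5×10³
counts/pixel/bin. The iodine high-bin value exceeds bone's relative
ordering because of the K-edge; the resulting 2×2 bone/iodine basis
matrix is well conditioned, which the `AttenuationTable` invariant
enforces (|det| > 10⁻⁶ × product of row norms).

**Energy subtraction.** The material-selective projections are weighted
log-domain differences that null the contaminant:
`bone_raw = P_low − (μ_I,low/μ_I,high)·P_high` and
`iodine_raw = P_low − (μ_B,low/μ_B,high)·P_high`. This is the simplest
scheme consistent with channel subtraction; the exact published variant
of silhouette subtraction is not public, so this realization is a stated
stand-in, not a claim about it. The residual soft-tissue term is
retained and absorbed into the quantization window. `exact_decompose`
(soft-tissue term subtracted, per-pixel 2×2 solve) is the analytic
oracle: on noiseless data it inverts the forward model to machine
precision, which both the tests and the acceptance script verify.

**Quantization.** 8-bit PNGs use dataset-wide windows frozen in the
manifest, computed as the 0.5/99.5 percentiles of each channel over a
small noiseless calibration batch. Per-image windows would destroy the
cross-image intensity comparability that MAE/PSNR assume. Rounding is
half-up (`floor(x + 0.5)`) for bit-exact reproducibility. The manifest
schema also freezes the conventional channel's window (two extra
columns) so inference-time normalization is reproducible from the
manifest alone.

## Networks

Canonical conditional-translation U-Net: 4×4 stride-2 convolutions,
LeakyReLU(0.2) encoder, ReLU decoders, batch normalization except on the
outermost and innermost layers, tanh output, N(0, 0.02) initialization.
Channel widths are `base · min(2^i, 8)`. Default depth is 8 at the
nominal 1024×512 resolution and 6 at the 64×64 test scale (bottleneck
1×1); base width 64 by default, 8 in the scaled-down study. One encoder
is shared; the two decoder heads are structurally identical, consume the
same bottleneck and skip tensors, and share no parameters — so a
bone-only loss has exactly zero gradient on the iodine head and a
generically nonzero gradient on the encoder, which the wiring tests
probe directly.

The stochastic input z has no published mechanism; the default is
dropout-as-noise (p = 0.5 in the first three decoder blocks), with an
explicit Gaussian input channel available as `noise_kind="channel"`, and
`off` for strictly deterministic mapping. Noise is always disabled at
inference. Discriminators never see z.

Discriminators are 70×70-receptive-field conditional PatchGANs (three
stride-2 layers, then two stride-1 layers), two independent instances
with private parameters. `receptive_field` documents the patch size by
the standard recursion.

## Objective and schedule

Adversarial terms use logit-space binary cross-entropy (overflow-safe by
construction) in the non-saturating form for the generator. The
reconstruction term is the plain L1 mean per head, summed. The
mutual-exclusivity term applies the logistic function to each head's
**scalar mean** cross-distance (not per pixel): the distances are
expectations, and one bounded reward per head keeps the sigmoid's
argument in a regime with usable gradient. Distances are computed in
the model's normalized [−1, 1] intensity range. Weights default to
(1, 100, 100).

The schedule ramps linearly 0 → 9×10⁻⁴ over the first 10 000 iterations;
"decay factor 0.9" is interpreted as multiplicative per completed
post-warm-up epoch (a *factor* implies multiplication; per-epoch is the
common granularity), floored at 5×10⁻⁶ and continuous at the warm-up
boundary. Both interpretation points are configurable.

## Training loop

Per iteration: update `D_b` on (input ‖ real bone) vs (input ‖ detached
bone prediction), then `D_c` likewise, then the generator with both
discriminators' parameters frozen. One schedule drives all three Adam
optimizers (β = 0.5/0.999). Non-finite losses abort with the offending
component named — silently skipping NaN steps would hide wiring bugs.
A single-head mode (one decoder, one discriminator, exclusivity ignored)
provides the one-material baseline within the same code path.

All random streams (initialization, dropout noise, batch shuffling,
Poisson sampling) are spawned from one seed; checkpoints carry network
parameters, batch-norm running statistics, optimizer moments, RNG states
and the step/epoch counters, making resumed runs step-for-step
equivalent to uninterrupted ones and full histories bit-reproducible.

## Evaluation

MAE, MS-SSIM, Pearson-R and PSNR are computed on the 8-bit 0–255 scale
(so MAE is in gray levels and PSNR uses MAX = 255), aggregated as mean ±
sample (n−1) standard deviation, with two-sided paired t-tests between
methods (significance reported at p < 0.05 and p < 10⁻⁴). MS-SSIM uses
the canonical 11×11 σ = 1.5 Gaussian window and 5-scale weights
(0.0448, 0.2856, 0.3001, 0.2363, 0.1333); at the 64×64 test scale only
3 scales fit (minimum dimension ≥ window·2^(scales−1)), so the first
three weights are renormalized — the scale count is a parameter. PSNR of
identical images is reported as +inf, and Pearson-R of a constant image
as NaN rather than 0. Line profiles sample bilinearly along segments in
(row, col) coordinates, origin top-left; the separation report scores
material retention (mean |conv − target head| along a single-material
line) and contaminant suppression (variance of the other head along the
same line).

## Scaled-down study conditions

The full-scale protocol (1440 projections of four subjects at 1024×512,
batch 4, 333 epochs) is far beyond desk scale, so the packaged study
uses: 200 noisy triplets (4 subjects × 50 views) at 64×64 with 400 μm
pixels (keeping path lengths, and hence contrast, comparable to full
scale), per-subject 80/20 split, depth-6 generator at base width 8,
batch 4, 400 steps with a 100-iteration warm-up, three seeds. Under
these conditions the trained model's held-out MAE falls well below the
identity baseline for both channels (direction, not magnitude, is the
claim), and the exclusivity-term ablation (λ₃ = 0 vs 100) is tabulated
across MAE/MS-SSIM/Pearson-R/PSNR as a report.

What the simulator does not emulate — polychromatic spectra, scatter,
detector cross-talk and charge sharing, real CdTe response, anatomical
texture — bounds what passing tests show about real data: they validate
the algorithmic contracts (physics inversion, wiring, objectives,
reproducibility, learnability of a projection-domain decomposition), not
in-vivo image quality.

## Numerical choices and edge cases

float32 parameters and activations for training; float64 for physics,
metrics and gradient checks. Zero counts clamp to one before the log.
Degenerate quantization windows are rejected (`lo < hi` required).
Center cropping uses floor offsets and never pads. The paired t-test
returns (t = 0, p = 1) for identical lists and an exact-tie sentinel
(infinite t, flagged) for zero-variance nonzero differences. Batch
normalization at 1×1 bottleneck spatial size is valid (statistics pool
over batch and space) but is omitted at the innermost layer following
the canonical recipe.

## Known limitations

The NumPy engine is single-threaded BLAS-bound and far slower than a GPU
framework, so full-resolution 333-epoch training is out of scope. The
phantom family is low-diversity compared with real anatomy; a model fit
on it will not transfer to clinical projections. Energy subtraction is
the idealized two-bin linear model; beam hardening and detector spectral
distortions are not represented.
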