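# Methods

This note records the models, conventions and numerical choices behind
`mwcam`, and what the synthetic experiments do and do not demonstrate.

## Physical model and conventions

The camera operates at f = 2.45 GHz in water (εr = 73, σ = 1 S/m).  All
wavenumber bookkeeping uses c = 3×10⁸ m/s and ε₀ = 8.8541878128×10⁻¹² F/m.
The lossless (real-part) water wavenumber is k_water = (2πf/c)·√73 ≈
438.4 m⁻¹, giving λ_water ≈ 14.3 mm and a retina spacing Δ = λ_water/4 ≈
3.58 mm; the 64-point spectral step is then exactly k_water/16.

Fixed conventions (every sign in the package follows from these):

* time dependence e^{+iωt}; spatial kernels e^{−i k·r}; outgoing 2D waves
  are Hankel functions of the second kind;
* the retina lies at y = d = 0.10 m, the observation plane at y = 0, and
  the unit incident plane wave travels toward +y as e^{−i k_water y}
  (its modulus is 1: medium loss is excluded from the incident phase);
* spectra are stored DC-centered on the even 64-grid (indices −32…31, DC at
  0-based index 32); the 17×17 crop is the symmetric −8…+8 window;
* γ = √(k²_water − k²_x − k²_z) is real and non-negative on the visible
  disk (inclusive boundary) and −i√(k²_x + k²_z − k²_water) outside, so
  evanescent components decay under e^{−iγd};
* the field spectrum is Δ² times the centered DFT — a Riemann sum of the
  continuous transform — so the diffraction relation holds with physical
  units and no hidden normalization constants.

On this grid the half-visible disk (radius k_water/2, inclusive) contains
exactly 197 lattice points inside a 17×17 bounding box; the full visible
disk contains 797.  Both counts follow from the inclusive-circle membership
rule on exact grid coordinates; the package asserts only the 197 count,
which is the operative one for the network input.

At the visible-domain rim γ = 0 (four lattice points), the diffraction
relation carries no current information: the forward kernel −i/2γ is
regularized to zero there and the inverse multiplies by 2iγ, so the
recovered current spectrum is exactly zero on the rim by construction.
Forward–inverse consistency is therefore exact (round-off level) on the
strictly propagative interior, and in particular on the half-visible disk.

## Forward solvers

**Born angular-spectrum solver (default).** Induced currents
j_z = (k² − k²_water)·E_i are formed per voxel with the *complex* water
k² (so an all-water phantom scatters exactly nothing), then each depth slab
is transformed over (x, z), multiplied by the Weyl kernel
(−i/2γ)·e^{−iγ(d−y′)} and accumulated with a midpoint rule in y.  With the
lossless kernel on the native 64×64 spectral grid this operator is the
exact discrete adjoint of the backpropagation formulas — which is what
makes the chain testable to 10⁻⁹ — at the price of the transverse
periodization every discrete spectral operator has.  Two controls expose
the physics instead: `medium="lossy"` propagates with the attenuating
water wavenumber (≈ 22 Np/m at 2.45 GHz), and `oversample=n` refines the
spectral step n-fold.  With loss and 4× oversampling the single-voxel
field matches a fine Riemann quadrature of the Weyl integral to ~3×10⁻⁸,
because attenuation makes the integral convergent and the periodized
copies negligible.  Without loss, the 1/r tail of the band-limited point
response aliases at the few-percent level for any practical oversampling;
this is a property of the discrete operator, not an implementation error,
and it is why the physical-kernel mode exists.

**2D full-wave slice solver.**  For multiple-scattering studies, the scalar
volume integral equation E_t = E_i + k²_w ∫ G₂D χ E_t dA is discretized on
pixels of at most λ_water/10 with Richmond's equal-area-disk cell
integration (self term −iπa/(2k)·H₁⁽²⁾(ka) − 1/k², smoothed off-diagonal
terms) and solved by FFT-accelerated LGMRES to a 10⁻¹⁰ residual.  The
induced currents are then propagated to the retina line with the same
angular-spectrum kernel as the Born solver.  Validation: total field of a
homogeneous tumor-like cylinder agrees with the cylindrical-harmonics
series to ≈ 0.5% at λ/16 pixels (boundary staircase ring excluded), and
the weak-contrast limit reproduces the Born solution to < 1% at
Δε/ε_w = 10⁻³.

**Noise.**  `add_awgn` draws circular complex Gaussian noise per retina
sample with total noise power equal to signal power / 10^(SNR/10),
deterministically from a seed.

## Phantom database

The database combines parametric surrogate solids: three superellipsoid
fat+skin shells (outer semiaxes 4–6.5 cm, skin thickness 2 mm), five
glandular inclusions (ellipsoids and ellipsoid unions, offset toward −x),
and five tumor shapes of 0.5–2 cm (spheres, ellipsoids, a two-lobe union).
Gland 5 is sized so it does not nest inside shell 1 — the single exclusion
that makes 3×5−1 = 14 tumor-free models — and every other pair nests with
positive clearance (verified numerically from boundary samples).  Four
tumor cases (none / adipose / glandular / both), mirroring (a true x → −x
reflection applied to the solid before simulation; it is not a half-turn
because the gland sits off the propagation axis) and 16 rotations about the
vertical axis give 56 × 2 × 16 = 1792 views.  Tumor shapes are assigned so
each shape pairs with a given cavity exactly once and a two-tumor phantom
never repeats a shape.  Tissue properties are the 2.45 GHz table values
(fat 5/0.1, glandular 44/1.5, skin 42/1.6, tumor 53/1.8 in εr / S·m⁻¹)
with one uniform ±5% draw per tissue property per model; mirrors and
rotations of a model share its draw, and water — the known calibration
medium — is never jittered.

A dedicated held-out phantom (a boxier superellipsoid shell, a three-lobe
gland, and a 1 cm tumor in the fatty region placed exactly on the
observation plane) supplies the 32-view test set; none of its solids occur
in the training combinatorics.  Splitting shuffles the 1792 combinatorial
views with a fixed seed and takes floor(0.8·1792) = 1433 for training and
359 for validation.

Voxelization uses the retina's transverse grid (64×64 at Δ) and 27 depth
slabs of thickness Δ centered on the observation plane; labels follow the
precedence tumor > gland > fat > skin > water and tissues are piecewise
constant.

## Normalization and calibration

Each sample pairs the backprojected, half-visible-filtered current image
with the reference contrast slice C = (ε′ − 73) − i(ε″ − ε″_w), where
ε″ = σ/(ωε₀).  Both images are min–max scaled per real and imaginary part
to [0, 1] (per image, no dataset pooling), transformed, filtered, cropped,
and divided by the maximum modulus on the 197-pixel mask — magnitudes
change, phases never do; real and imaginary spectrum entries end in
[−1, 1] with maximum modulus exactly 1.  One subtlety worth recording: the
per-part min–max range is an order statistic, so in-band noise perturbs
the affine map itself; for the imaginary part (an order of magnitude
smaller than the real part in these phantoms) a 10 dB field SNR moves the
normalized imaginary input by ~50–65% as a *global amplitude shift*.  The
water calibration downstream removes exactly such global shifts, which is
why robustness is judged on calibrated maps (below).

Denormalization embeds the 17×17 network output into the full grid,
inverse-transforms, and calibrates against the coupling medium: with M_ℜ,
M_ℑ the means of the real/imaginary parts over outside-phantom pixels,
ε_cal = (ℜC_net/M_ℜ)·73 and σ_cal = (ℑC_net/M_ℑ)·1.  This grouping makes
the water region a fixed point of the calibration — the alternative
grouping (ℜ/M − 1)·ε_w would map water to zero, defeating the purpose —
and makes the maps invariant to any global rescaling of the network
output.  A second min–max pass then maps ε_cal affinely onto
[min|ε_cal|, max|ε_cal|]; the conductivity uses the mirrored affine form
(max|·| down to min|·|), implemented exactly as specified even though the
mirror inverts the ordering; both maps are therefore non-negative.
Finally the contour prior overwrites all outside-phantom pixels with the
exact water values (73, 1 S/m).  The contour is taken from the reference
phantom, i.e. it is prior knowledge, not an estimate.

Feeding the reference spectrum itself through this chain (the perfect-
network bound) recovers water exactly outside the contour and an
in-phantom permittivity that correlates with the truth at ~0.7–0.9
depending on the phantom; the gap is the cost of 197-pixel truncation plus
the affine calibration, and bounds what any network output can achieve.

## Networks and training

Each of the two networks maps one real 17×17 channel to one real 17×17
channel.  Encoder: four [BatchNorm → ReLU → Conv] blocks with kernels
9/7/5/3 and paddings 2/2/1/0 (the very first block omits the ReLU — its
inputs are signed values in [−1, 1]), producing sizes 13, 11, 9, 7 with
feature counts growing 32 → 256 at default width.  The bottleneck is a
dense linear layer (flatten 256·7·7 → same size; a channelwise 49→49
variant shares one linear map across channels and is used at desk scale).
Decoder: four k = 3 blocks with paddings 2/2/2/3 whose inputs concatenate
the previous output with the same-size encoder output (7↔7, 9↔9, 11↔11,
13↔13), restoring 17×17; a 1×1 convolution projects to one channel.  The
size arithmetic out = in − k + 1 + 2p is asserted at build time.

Training: Adam with lr 10⁻³ and β = (0.9, 0.999), batches of three, 30
epochs, WMAPE loss; the half-visible mask multiplies both the network
input and output, so off-support pixels contribute to neither sum of the
loss.  All randomness (weights, shuffling) derives from explicit seeds;
layers support float32 to halve memory traffic in desk-scale runs.

Two empirical properties of this setup are worth knowing.  First, with
batch size 3 the batch-normalization statistics jitter from batch to
batch, which leaves a WMAPE floor of roughly 0.11–0.15 on even a pure
identity task at the widths tested here; the capacity test asserts
convergence against that floor (loss < 0.2 and an 80% drop from epoch 1)
rather than an arbitrary smaller figure.  Second, the L1-type loss yields
constant-magnitude sign gradients, so convergence speed is governed by the
optimizer step count, not the loss scale.

## Evaluation

SSIM uses the Gaussian-window convention (window 11, σ = 1.5, k₁ = 0.01,
k₂ = 0.03) with data range max − min of the reference; PSNR uses
10·log₁₀(range²/MSE) with the same range.  Metrics are computed on the
real and imaginary parts of the 17×17 spectra for the network input
(ĵ_norm vs Ĉ_norm) and output (Ĉ_net vs Ĉ_norm), per batch of three
(full batches drive the curves; remainder samples enter only the dataset
means), and — as the image-domain report — on the calibrated (εr, σ) maps
against the maps implied by the reference contrast.

Noise robustness is judged on the calibrated maps: networks are trained
noise-free, test inputs carry 10 dB AWGN, and the mean map SSIM shift is
required to stay below 0.1.  The spectral-domain input/output SSIMs under
noise are still reported, but they conflate reconstruction quality with
the min–max order-statistic shift described above.

## Desk-scale study conditions

The full database (1792 + 32 views) simulates in a few minutes, but tests
and examples use a reduced study chosen once: one rotation per model (112
combinatorial samples, split 89/23) plus 8 held-out views; networks of
widths (8, 16, 32, 64) with the channelwise bottleneck in float32; 30
epochs, batch 3, lr 10⁻³.  Under these conditions training decreases WMAPE
from ≈ 3.6–4.2 to ≈ 0.36–0.38, held-out output SSIM exceeds input SSIM on
both parts (e.g. 0.91 vs 0.74 real, 0.88 vs 0.40 imaginary on validation),
and 10 dB input noise shifts mean calibrated-map SSIM by ≈ 0.03 (εr) and
≈ 0.07 (σ).

## Limitations

* The forward default is first-Born: multiple scattering inside the breast
  is absent from the training data (the 2D full-wave solver exists to probe
  that mismatch, not to generate the 3D database).
* Depolarization is neglected by construction (scalar model); the dyadic
  operator is out of scope.
* The surrogate cavities are parametric stand-ins with the right
  combinatorics, sizes and dielectric values, not anatomically derived
  geometry; absolute image-quality numbers therefore characterize this
  synthetic family only, and passing tests demonstrate chain correctness
  and qualitative behavior, not clinical performance.
* The contour prior assumes the phantom support is known exactly.
* Single frequency, single view: no multi-frequency or volumetric spectral
  coverage.
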