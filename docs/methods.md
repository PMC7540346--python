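# Methods

## Signal model and estimator

A recorded photoacoustic channel is modeled as
`x = s_low + s_sparse + w`: a slowly varying background, a sparse or
sparse-derivative component carrying the acoustic transients, and white
Gaussian noise.  Because a zero-phase low-pass filter L commutes (to a
good approximation) with the decomposition, the background can be
eliminated analytically — `s_low ≈ L(x − s_sparse)` — leaving a
single-variable convex program for the sparse component:

    u* = argmin_u  ½‖H(x − u)‖² + λ₀‖u‖₁ + λ₁‖Du‖₁ ,     H = I − L,

with D the (N−1)×N first-difference operator.  The denoised channel is
`u* + L(x − u*)`, which equals `Lx + Hu*`: the low band of the data passes
through untouched while the high band is replaced by its sparse estimate.
Two structural consequences are worth keeping in mind when interpreting
benchmark numbers:

* noise inside the low-pass band is never removed — the method's MSE gain
  is capped by the in-band noise fraction (≈17% of the noise power at
  f_c = 0.1 with the default filter), i.e. ≈7–8 dB;
* the sparse stage only acts on signal content above the cutoff, so the
  emitted-pulse bandwidth decides how much work it can do (see
  "Synthetic data" below).

## Filter

H is the classic zero-phase non-causal recursive high-pass built from
banded matrices: `B = FᵀF` with F the d-fold first difference (valid rows
only), `C = GᵀG` with G the d-fold first sum, and `A = B + αC` with
`α = tan(π f_c)^{2d}`, giving

    H(ω) = (2 sin ω/2)^{2d} / [ (2 sin ω/2)^{2d} + α (2 cos ω/2)^{2d} ],

a monotone response with a 2d-order zero at DC, unity at Nyquist, and
magnitude exactly ½ at f_c (half-power convention).  The finite-signal
operator uses no padding: F annihilates polynomials of degree < d, so
constants (and linear trends for d ≥ 2) are blocked exactly at the
boundaries too.  A is symmetric positive definite and banded; application
is a cached banded Cholesky solve.  Near the signal ends the effective
smoothing is one-sided, so low-passed noise retains more variance there —
visible as occasional boundary excursions in denoised channels.

Defaults: f_c = 0.1 cycles/sample for the ring-array simulation and 0.15
for the sector-probe preset; d = 2.  The accepted f_c range is roughly
0–0.3 cycles/sample; deviations up to ~20% from the best cutoff are
partially compensated by the sparse stage.

## Solver

Consensus ADMM with two copies of u.  The u-update solves
`(HᵀH + 2ρI)u = HᵀHx + ρ(z₁−d₁+z₂−d₂)` exactly via the substitution
`q = A⁻²B(x−u)`, which turns it into the banded SPD system
`(A² + B²/2ρ) q = B(x − w/2)` — no dense matrix is ever formed.  The z
updates are the exact proximal maps: soft thresholding at λ₀/ρ and direct
1-D total-variation denoising at λ₁/ρ (a taut-string-class single-pass
algorithm, exact up to floating point; verified in the tests against an
independent dual box-constrained least-squares solver).  Optional
over-relaxation (α = 1.8) accelerates the consensus step.  Stopping uses
relative primal/dual residuals (tol = 1e−6, max_iter = 200); residual
blow-up beyond 10⁶× the initial residual is reported as non-convergence
with the partial result flagged.

Per-iterate objectives of ADMM are not monotone in general, so
`DenoiseResult.cost_trace` reports the objective of the *incumbent*
(best-so-far) iterate, which is nonincreasing by construction, and the
returned estimate is that incumbent; first-order optimality of the final
state is certified separately via the exact subgradient property of the
scaled duals (`ρd ∈ ∂g(z)` after each prox step).

### Amplitude calibration

RF amplitudes are arbitrary, so λ₀ = λ₁ = 1 only means something relative
to a per-channel scale.  Peak scaling (unit maximum amplitude) is
degenerate here: the filter satisfies ‖HᵀH‖ ≤ 1, so with max|x| = 1 the
zero vector already satisfies the optimality condition
|HᵀHx|∞ ≤ λ₀ and the sparse stage never activates.  The package therefore
calibrates each channel by its robust noise-level estimate
`σ̂ = median(|Hx|)/0.6745` (the high-passed channel is noise-dominated
away from sparse features), making λ = 1 a one-sigma penalty — the
standard calibration in total-variation and wavelet shrinkage practice.
The estimate is amplitude-homogeneous, so doubling a channel exactly
doubles the output.  Within λ ∈ [0.8, 1.2] the output RMSE on the
generative model varies by only a few percent (tested).

## Baselines

* **Frame averaging**: elementwise mean of K independent acquisitions;
  noise std shrinks by √K (Monte-Carlo-verified).  Note that with truly
  independent frame noise this is a very strong baseline — 20 frames
  remove 13 dB of noise power everywhere in the spectrum, which a
  single-frame band-selective method cannot match in MSE.  Averaging in
  real systems is weaker because part of the noise is coherent across
  frames; that regime is not modeled here.
* **Wavelet shrinkage**: Symlet-6, 6 decomposition levels, soft
  thresholds chosen per level by minimizing Stein's unbiased risk
  estimate, σ estimated by MAD of the finest detail band / 0.6745,
  symmetric boundary extension (PyWavelets).

## Synthetic data

The generator emulates a tomographic in-silico study: a 512×512 vascular
initial-pressure map on a 10-mm grid (seeded momentum-biased random-walk
vessel trees, widths ~1–6 px, values in [0,1], confined well inside the
ring), received by a 60-element 9-mm-diameter circular array of point
detectors, 1019 samples at 9.259 ns (108 MHz), sound speed 1500 m/s.
Physical-phantom presets: two 150-µm filaments 1 mm apart, and three 1-mm
tube cross-sections at 10/15/20 mm depth for a 64-element 9-mm sector
probe (with exponential depth decay, µ_eff = 150 m⁻¹, emulating fluence
loss in tissue).

The forward model is an analytic point-source superposition — each
nonzero pixel radiates the emitted pulse delayed by its time of flight
with 1/r spreading (r floored at one pixel) — in a homogeneous,
non-attenuating medium.  The default pulse is a broadband Ricker wavelet
(spectral peak 12 MHz): even and bipolar, so a point source's recorded
peak lands exactly at its nominal delay, and broadband like the sharp
N-shaped transients that wideband point sensors record from small
absorbers — which is what gives channels the sparse-derivative structure
the denoiser assumes.  A band-limited Gabor pulse is available for
emulating physical transducers; note that with a narrowband pulse whose
spectrum sits below f_c the sparse stage has (correctly) nothing to do
and LPFSC reduces to its low-pass half.

Noise is white Gaussian, calibrated on the whole-frame mean power:
`10·log10(P_signal/P_noise) = SNR(dB)`, deterministic per seed.

What the generator does **not** model — and hence what passing tests do
not establish about real data: full-wave propagation (reflections,
mode conversion, grid dispersion), frequency-dependent attenuation,
acoustic heterogeneity, transducer impulse responses and directivity,
coherent/fixed-pattern noise, and laser energy fluctuations.

## Reconstruction and metrics

DAS: per pixel, sum over elements of the linearly interpolated RF sample
at the one-way time of flight (uniform weighting, no apodization;
out-of-window delays contribute zero), then envelope detection along
depth (analytic-signal magnitude per column) and peak normalization.
Point targets localize within one pixel on the default 128×128, 10-mm
grid (tested over random positions).

Metrics follow fixed conventions: PSNR defaults to `20 log10(S_max/MSE)`
(the printed-formula convention; the standard RMSE form is selectable),
with S_max = max|reference|; SSIM is the single global-statistics formula
with c₁ = (0.01L)², c₂ = (0.03L)², L the joint dynamic range; CNR is
`20 log10(|S_i − S_o|/σ_o)` over rectangular ROIs; FWHM interpolates the
half-maximum crossings nearest the profile peak.  Because PSNR in the
printed convention is scale-dependent, benchmarks evaluate it on
unit-peak-normalized clean frames.

## Benchmark design

All drivers are reproducible bit-for-bit from (config, seed); noise seeds
are shared across SNR levels (common random numbers) so level-to-level
comparisons are paired.  The image benchmark references every method's
reconstruction to the clean-signal reconstruction (so SSIM measures
denoising quality, not reconstruction blur), and derives its CNR ROIs
from that clean reference: the target box sits on the brightest vessel,
the background box in the quietest in-ring region.  Signal benchmarks use
SNR ∈ {10, 5, −5, −10} dB; image benchmarks {5, 10, 15, 20} dB; headline
percentage comparisons average 10 noise draws per level.  The frames
sweep compares n-frame averaging with LPFSC applied to the same n-frame
average (n = 1…7) against a 10-frame-average reference at 0 dB
single-frame SNR — a realistic single-shot level for deep tissue targets.

Problem sizes throughout (512² phantom, 1019×60 frames, 10 draws per
level, 128² images) are the package's native benchmark conditions; a full
acceptance run takes a few minutes on one CPU.

## Known limitations

* The in-band noise floor caps single-frame MSE performance (see above);
  with ideal independent-frame noise, 20-frame averaging outperforms any
  single-frame method in plain MSE/PSNR, and SURE-calibrated wavelet
  shrinkage — which thresholds all bands — is a strong single-frame
  competitor.  LPFSC's advantages concentrate where they matter for
  images: flat, artifact-aware backgrounds (CNR) and structural fidelity
  at low SNR (SSIM).
* Peak-amplitude recovery at very low SNR is biased by the one-sigma
  shrinkage: at −10 dB the strongest channel peak is only a few σ and
  narrow, so relative peak errors of ~20–30% are expected under this
  calibration; boundary noise excursions can additionally offset the
  measured maximum.
* Background CNR at high input SNR is limited by coherent DAS sidelobe
  artifacts that no signal-domain denoiser removes; post-denoising CNR is
  therefore nearly flat in input SNR and can peak at mid SNR, where the
  noise-adaptive threshold flattens the background hardest.
* The exact 1-D TV prox assumes the first-difference operator; 2-D
  (cross-channel) coupling is out of scope.
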