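# lpfsc — photoacoustic signal denoising by low-pass filtering + sparse coding

Photoacoustic (PA) imaging converts pulsed-laser absorption into ultrasound
and suffers from low signal-to-noise ratio: thermal, transducer and
electronic noise bury the radio-frequency (RF) channel signals, and the
standard remedy — averaging many repeated acquisitions — costs frame rate.
`lpfsc` implements a single-frame alternative: **LPFSC**, simultaneous
low-pass filtering and ℓ₁/total-variation sparse coding, for researchers
working on PA/ultrasound signal processing who want a reproducible in-silico
testbed for denoising and image-quality comparisons.

## The model

A noisy PA channel is modeled as

    x(n) = s_low(n) + s_sparse(n) + w(n),

a low-frequency component plus a sparse / sparse-derivative component plus
white Gaussian noise.  Applying a zero-phase recursive high-pass filter
H = A⁻¹B (banded, DC-blocking, |H| = ½ at the cutoff f_c) eliminates the
low-frequency component analytically, leaving the convex program

    min_u  ½‖H(x − u)‖₂² + λ₀‖u‖₁ + λ₁‖Du‖₁,

where D is the first-order difference.  The solver is consensus ADMM: two
copies of `u` receive the exact proximal maps of the two penalties (soft
thresholding and a direct taut-string-class 1-D TV solver), and the
u-update is an exact banded symmetric-positive-definite solve
(A² + B²/2ρ) — every subproblem is closed-form and O(n), with no
randomness.  The low-frequency part is then recovered as
`s_low = lowpass(x − u*)` and the denoised channel is `u* + s_low`.

Around the solver the package provides everything needed for a full
in-silico benchmark: a seeded vascular/filament/tube phantom generator, an
analytic point-source forward model for circular / linear / phased arrays
(60-element 9-mm ring, 1019 samples at 108 MHz by default), calibrated
white-noise injection, frame-averaging and Symlet-6 SURE wavelet baselines,
delay-and-sum (DAS) reconstruction with envelope detection, and the
PSNR / global-SSIM / CNR / FWHM metrics.

## Worked example

```python
import numpy as np
import lpfsc as L

phantom  = L.make_vessel_phantom(512, seed=7)          # 10-mm vascular map
geometry = L.circular_array()                          # 60 elements, 9 mm ring
clean    = L.forward_simulate(phantom, geometry)       # 1019 x 60 RF frame
clean    = clean.with_data(clean.data / np.max(np.abs(clean.data)))
noisy    = L.add_noise(clean, L.NoiseSpec(snr_db=-5.0, seed=0))

den = L.lpfsc_denoise_frame(noisy, L.LPFSCConfig(fc=0.1, lam0=1.0, lam1=1.0))
print('PSNR noisy   : %.1f dB' % L.psnr(clean.data, noisy.data))
print('PSNR denoised: %.1f dB' % L.psnr(clean.data, den.data))

ref = L.das_reconstruct(clean, geometry)
img = L.das_reconstruct(den, geometry)
print('SSIM vs clean reconstruction: %.3f' % L.ssim_global(ref.pixels, img.pixels))
```

prints

```
PSNR noisy   : 40.8 dB
PSNR denoised: 53.5 dB
SSIM vs clean reconstruction: 0.640
```

i.e. at −5 dB input SNR the denoiser gains ~13 dB of signal PSNR
(printed-formula convention, S_max/MSE) and the DAS image of the denoised
frame is structurally closer to the clean-signal reconstruction than the
noisy one (SSIM 0.64 vs 0.51 for this phantom seed).

A thin CLI wraps the same functions:

```sh
lpfsc simulate --phantom vessel --seed 1 --snr-db 5 --out frame.rf
lpfsc denoise frame.rf --method lpfsc --fc 0.1 --out den.rf
lpfsc recon den.rf --geometry circular --grid 128 --out den.tif
lpfsc benchmark signal --seed 0 --out-dir bench/
```

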