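# sfsc — self Fourier shell correlation

The Fourier shell correlation (FSC) is the standard similarity measure of
structural biology: the normalized cross-correlation of two signals computed
over radial shells in the frequency domain, used everywhere for resolution
estimation and spectral signal-to-noise (SSNR) estimation.  Computing it
normally requires **two** independent measurements of the same signal (half
maps in single-particle cryo-EM).  Many workflows — cryo-electron tomography,
manifold-embedding reconstructions, 2-D class averages — produce only one.

`sfsc` estimates the FSC and SSNR from a **single** noisy measurement
`y = x + ε`.  The measurement is decimated into even- and odd-index samples
along each axis; the two half-size grids see the same underlying signal, so
their shell correlation — the *self FSC* (SFSC) — carries the same
information as a half-map FSC, provided the statistics cooperate.  Under a
mean-zero Gaussian model with shell-wise Fourier variances λ²(r) (signal)
and σ²(r) (noise), the expectation of the SFSC at shell *k* of the decimated
grid is

    ESFSC[k] = (λ²[k] − λ²[k′] + σ²[k] − σ²[k′]) / (λ²[k] + λ²[k′] + σ²[k] + σ²[k′]),

where `k′ = k + N/2` is the aliasing partner folded in by decimation.  When
the noise is white and the signal spectrum decays rapidly this reduces to
`λ²/(λ² + 2σ²)` — the FSC with the noise variance doubled — and the
correction `EFSC = 2·ESFSC/(1 + ESFSC)` recovers the familiar
`EFSC = λ²/(λ² + σ²)`, hence `SSNR = EFSC/(1 − EFSC)`.

When the statistics do not cooperate, the package provides the corrections
that restore the estimate:

- **phase alignment** — the odd half lags the even half by half a voxel; its
  spectrum is rotated by `exp(−2πik/N)` before correlating (otherwise the
  curve of a smooth image follows a scaled Bessel function J₀);
- **noise whitening** — σ²(r) estimated from a signal-free region (outside
  a sphere enclosing the particle, or a background slab of a tomogram)
  flattens colored noise without changing the per-shell SSNR;
- **Fourier upsampling with noise subtraction** — for slowly decaying
  spectra, zero-padding to 2N empties every aliasing partner, and
  subtracting the known (whitened) noise term γ from the correlation
  numerator turns the SFSC into a direct estimate of the EFSC over the full
  frequency range.

Downstream, the package reads off the global resolution at the single-map
`FSC = 1/7` threshold and applies the data-driven Wiener filter
`x̂_WF = EFSC(r)·ŷ` for denoising — the main practical payoff in cryo-ET,
where no second measurement exists.

## Worked example

Estimate resolution from a single synthetic measurement (64² image,
0.5 Å/pixel, B = 100 Å² signal decay, white noise, SNR 15):

```python
import numpy as np
from sfsc import *

spec = SyntheticSpec(shape=(64, 64), voxel_size=0.5, b_signal=100.0, snr=15.0, seed=1)
y, truth = sample_measurement(spec)

report = diagnose(y)                      # flat-tail preprocessing check
print(f"flat tail: {report.flat} (cv={report.cv_upper_half:.3f})")

curve = variance_correction(sfsc(y))      # per-axis SFSC on the EFSC scale
res = resolution_at_threshold(curve)      # first 1/7 crossing
print(f"resolution at FSC=1/7: {res.resolution:.2f} A ({res.status})")

efsc = efsc_closed_form(truth.lam2, truth.sig2)
print(f"model EFSC crossing:   {resolution_at_threshold(efsc).resolution:.2f} A")
```

prints

```
flat tail: True (cv=0.065)
resolution at FSC=1/7: 2.50 A (crossed)
model EFSC crossing:   2.39 A
```

The single-measurement estimate lands within one shell of the analytic
crossing of the generative model.  Denoising a 3-D phantom (64³, SNR 0.5)
with the whiten → upsample → SFSC → Wiener pipeline:

```python
y = RealGrid(ph.values + noise, 0.5)                  # phantom + white noise
curve = sfsc_upsampled(whiten(y, noise_model))
denoised = wiener_filter(y, curve).filtered
```

reduces the mean squared error against the clean phantom from 0.0332 to
0.0005 (seed 1), within ~2% of the oracle Wiener filter built from the true
spectrum.

## Command line

```sh
sfsc simulate --spec spec.json            # draw synthetic measurements
sfsc sfsc vol.mrc --whiten-sphere 115 --upsample     # curve CSV/JSON
sfsc resolution vol.mrc --threshold 0.142857
sfsc denoise tomo.mrc --noise-slab 0:10:40 -o tomo_denoised.mrc
sfsc fsc half1.mrc half2.mrc
```

Exit codes: 0 success, 1 data error, 2 usage error.  All runs log their
parameters and seeds.

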