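# Methods

## Model

All estimators assume the measurement model `y = x + ε` on a d-dimensional
lattice (d ∈ {1,2,3}) with uniform voxel size V (Å).  Signal and noise are
mean-zero Gaussian with diagonal Fourier covariances whose entries are
constant on radial shells: per-coefficient variances λ²(r) and σ²(r).  The
spectral signal-to-noise ratio is SSNR(r) = λ²(r)/σ²(r); the deterministic
expectation-FSC is EFSC(r) = λ²(r)/(λ²(r)+σ²(r)) and SSNR = EFSC/(1−EFSC).

## Conventions

- **DFT**: unitary (`norm="ortho"`), so Parseval holds without factors and
  unit-variance white noise has a flat radial power spectrum equal to 1.
  All variance statements (e.g. "σ² = 1 after whitening") are in this
  convention.
- **Shells**: label `r = round(‖k‖₂)` on centered signed integer
  frequencies; indices beyond the inscribed ball `‖k‖ > min(shape)/2` (the
  Fourier-cube corners) carry no shell — they would form incomplete,
  anisotropic shells.  Shell r sits at physical frequency
  `r/(min(shape)·V)` Å⁻¹.  Where a radial profile must act on *every*
  coefficient (synthesis, whitening, Wiener gains) the corner indices reuse
  the outermost shell's value.
- **Radial power spectrum**: the *mean* of |ŷ[k]|² over the shell, not the
  sum.  The FSC itself is scale-free, so this choice only fixes the units of
  noise profiles, which are always used ratio-wise.
- **Decimated grids**: even/odd splitting halves one axis and doubles the
  stored voxel size.  For square parents the index-shell convention then
  reproduces the parent's physical frequency axis exactly: shell r of the
  decimated grid is shell r of the parent, covering half the parent range.
  Non-square parents are supported but the averaged curve is truncated to
  the shortest per-axis curve; strongly anisotropic use is out of scope.

## Estimators

**SFSC** (`sfsc`): for each axis, split even/odd, phase-align, correlate per
shell, then average the d per-axis curves (unweighted; undefined shells are
excluded from the mean).  The odd half lags the even half by one parent
voxel — half a decimated voxel — so its spectrum is multiplied by
`exp(−2πik/N)` (centered k of the decimated grid, N the parent length).
The sign follows from the decimation identity
`ŷ_o[k] = ω_N^{−k}(ŷ[k] − ŷ[k+N/2])/2`; with the wrong sign the correlation
of a smooth radial image would not stay near 1.  Without the correction it
follows the scaled Bessel function J₀(2πr/N), dipping to J₀(π/2) ≈ 0.47 at
the decimated Nyquist.  (The misalignment phase never exceeds π/2 in
magnitude for a half split, so the unaligned curve cannot cross zero.)

**Closed-form expectation** (`esfsc_closed_form`): the expectation ratio is
evaluated per index and summed over the shell — the aliasing partner of
multi-index k under an axis-a split is `k + (N_a/2)·ê_a`, whose radius
varies within a shell for d ≥ 2 — and reduces to the printed per-shell form
in 1-D.  Because the synthetic sampler and the oracle use the identical
corner extension, the oracle is exact for sampled fields (up to the
ratio-estimator bias below).

**Variance correction** (`variance_correction`): v → 2v/(1+v), mapping the
white-noise/rapid-decay SFSC scale onto the EFSC scale.  v = −1 is a pole
and becomes undefined; double application is an error.

**Checkerboard mode** (`sfsc_checkerboard`): keeps the all-even and all-odd
parity classes across every axis simultaneously (the historical scheme).
Retained for comparison only: it inflates the effective noise variance by
2^d instead of 2, which the validation suite confirms by fitting c in
`mean SFSC ≈ λ²/(λ²+c·σ²)` (c ≈ 2 per-axis, c ≈ 4 checkerboard in 2-D).
Its alignment phase is diagonal (one parent voxel along every axis).

**Whitening** (`noise_whitening`): every coefficient is divided by the shell's
√σ².  Radial, hence Hermitian-symmetric: output stays real.  Per-shell SSNR
is invariant.  Noise profiles come from: the region outside a centered
sphere (power rescaled by total/outside voxel count — without this the
masked fraction's power loss biases the level low); a background slab, whose
power is accumulated in *physical*-frequency bins (a thin slab's raw index
shells would mix physically different frequencies) with a Hann taper along
the cut axis (a hard slab edge leaks low-frequency power into the tail
through sinc² sidelobes) and transferred to the parent shells by linear
interpolation in frequency; or a known profile.  A floor of 1e−12 relative
to the profile maximum guards the division, with a logged warning.
The slab's frequency resolution is 1/(thickness·V); it must resolve the
noise spectrum's variation, so steep spectra need thick slabs.

**Upsampled estimator** (`sfsc_upsampled`): the whitened measurement is
Fourier-upsampled ×2 (per-axis zero padding via `scipy.signal.resample`,
which splits the even-length Nyquist bin to keep the result real; values at
original sample positions are preserved).  Every retained frequency's
aliasing partner is then deterministically zero, so the decimated halves are
identical up to phase and correlate to 1; subtracting the known noise term
γ per coefficient from the numerator leaves a direct EFSC estimate over the
full original range.  In the unitary convention with value-preserving
upsampling the noise term per retained coefficient is γ = 2^(d−1)·σ²_w
(σ²_w = 1 after whitening); the subtraction uses n_r·γ because the shell
numerator is a sum while γ is per-coefficient.  Shells above the original
Nyquist carry only padding and are not produced.

**Resolution** (`resolution_at_threshold`): first downward crossing of the
threshold (default 1/7) scanning low→high frequency, linearly interpolated
between the bracketing shells; never-below returns the Nyquist resolution
with a flag, below-at-start is undefined with a flag.  First crossing, not
last: robust to high-frequency noise in the curve.

**Wiener filter** (`wiener_filter`): the minimum-MSE gain SSNR/(1+SSNR)
equals the EFSC, so ŷ is multiplied shell-wise by the variance-corrected
curve clamped to [0,1] (negative correlations carry no usable gain; using a
raw curve would double-count the noise and is allowed only explicitly).
Gains map to the parent shells by frequency interpolation, zero beyond the
curve's range; the DC coefficient passes through unchanged (the mean is not
an estimation target of the shell model).  Optionally a hard low-pass at the
1/7-threshold resolution is appended.

**Diagnostics** (`diagnose`): the white-noise/rapid-decay regime shows an
approximately constant upper-half power spectrum.  The upper half is
averaged in 4 coarse count-weighted bins before taking the coefficient of
variation (per-shell chi-square noise on a single 64² image is ~12% and
would swamp the default cv < 0.1 threshold); a non-flat verdict recommends
whitening, a flat verdict with weak overall decay recommends upsampling.

## Synthetic data

`SyntheticSpec` defaults are the package's standard study conditions: 64²
grids (32³/64³ for volumes) at V = 0.5 Å, B_signal = 100 Å², white noise
(B_noise = 0), SNR 15 (real-space variance ratio — the conventional
reading), seed 0.  These are scaled-down analogues of the 360²/0.81 Å
images the method is aimed at; the voxel size is chosen so that the
B-factor decay relative to the SFSC band edge matches the intended regime —
real projection images carry intrinsic spectral decay on top of the applied
B-factor, which a flat-base Gaussian field lacks.  B-factor attenuation
multiplies amplitudes by exp(−B s²/4) (the crystallographic convention), so
per-coefficient variances decay as exp(−B s²/2).

Coefficients are complex Gaussian, Hermitian-symmetrized (self-conjugate
frequencies come out real with the correct variance), DC set to zero
(mean-zero model), per-index standard deviation taken from the shell
profile with the corner extension.  Corner energy matters: without it,
nominally white noise is not white under decimation (the folded-in aliasing
partners of near-axis coefficients lie in the corners) and the
noise-doubling identity c = 2 fails.

What the generator does *not* emulate: contrast transfer functions,
missing-wedge anisotropy, spatially varying (non-stationary) noise, masking
correlations, and the non-Gaussian structure of real specimens.  Passing
tests therefore demonstrate correctness of the estimators under the stated
model, not robustness to those effects; for non-uniform noise the method is
expected to fail, and `diagnose` only detects (not models) the violation.
The deterministic `phantom` (soft-edged spheres and a ring confined to the
central half of the box) stands in for structured specimens in the Wiener
benchmark; `smooth_radial_field` provides an exactly radial band-limited
spectrum, defined directly in Fourier space, for the phase-alignment
diagnostics (a real-space blob's box truncation creates a spectral floor
that decorrelates the halves at high shells).

## Statistical conventions of the validation suite

- Shell r = 0 (a single coefficient with the mean removed) and the edge
  shell of a decimated curve (whose aliasing partner has the same radius, so
  the expectation numerator vanishes identically) are excluded from curve
  comparisons.
- The FSC-type ratio estimator carries O(1/n_r) small-sample bias relative
  to the ratio-of-expectations closed form; Monte-Carlo-vs-closed-form
  comparisons therefore restrict to shells with n_r ≥ 30, and sweeps with
  hundreds of shell comparisons use a familywise allowance (≥95% of shells
  within 3 SE, all within 5 SE) rather than demanding every z < 3, which a
  correct implementation would fail by chance.
- Nonlinear maps of curves (the variance correction in the condition-matrix
  comparisons, the SSNR conversion in the recovery experiment) are applied
  to the *mean* curve rather than averaged over per-draw transformed curves:
  2v/(1+v) is concave (per-draw averaging is biased low by Var(v)) and
  v/(1−v) is convex with exploding bias near v = 1.  Delta-method standard
  errors accompany the converted means.
- The Wiener benchmark is 3-D: with ~4πr² coefficients per shell the
  single-measurement gain estimate is nearly noiseless and the filter lands
  within ~2% of the oracle's MSE.  In 2-D at 64² the per-shell gain noise
  leaves ~20–25% excess MSE — a real property of the estimator at small
  image sizes, not an implementation artifact.

## Problem sizes and runtime

Validation experiments use 64² images (500 draws for the inflation fits,
300 per profile pair for the oracle sweep, 100 per figure condition), 32³
volumes (200 draws, SSNR recovery) and one 64³ phantom benchmark
(100 draws).  The full suite runs in a few minutes on one CPU;
`scripts/acceptance.py` takes about a minute.

## Known limitations

- Uniform voxel size only; strongly non-square grids give truncated
  averaged curves.
- Odd axis lengths are rejected, never silently cropped (cropping changes
  the frequency axis and is the caller's explicit decision).
- Corner-based noise estimation is invalid for maps masked during
  reconstruction; the flat-tail diagnostic warns but cannot repair this.
- The 1-D "checkerboard" degenerates to the axis split and is rejected.
- `lowpass` applies a continuous-frequency cutoff, so at exactly the
  Nyquist cutoff the corner coefficients beyond the inscribed ball are
  removed in d ≥ 2 (in 1-D it is the identity).
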