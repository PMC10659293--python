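"""Generative model for testing the estimators without external data.

Fields are mean-zero Gaussian with a diagonal Fourier covariance constant on
shells.  Spectral decay follows the crystallographic B-factor convention:
amplitudes attenuate as ``exp(-B s^2 / 4)`` at spatial frequency ``s`` in
1/Angstrom, so per-coefficient variances decay as ``exp(-B s^2 / 2)``.
Measurements are ``y = x + eps`` with the noise drawn the same way (white
when ``b_noise = 0``) and scaled to a target real-space variance ratio
``Var(x)/Var(eps) = snr``.

Sampling covers the full Fourier cube: the radial profile is extended to the
corner indices beyond the inscribed Nyquist ball by clamping the shell label
at ``R = min(shape)//2``.  Without corner energy, nominally white noise
would not be white under decimation (its aliasing partners would vanish),
breaking the noise-variance-doubling identity the estimators rely on.  The
closed-form oracles use the same extension, so they are exact for these
fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .fourier import (
    RealGrid,
    RadialProfile,
    ShellBinning,
    build_shells,
    extended_labels,
)


@dataclass
class SyntheticSpec:
    """Parameterization of the generative model.

    Defaults are the package's scaled-down standard conditions: 64^2 grids at
    0.5 A/voxel with a B = 100 A^2 signal decay, white noise and snr 15.
    """

    shape: tuple[int, ...] = (64, 64)
    voxel_size: float = 0.5
    b_signal: float = 100.0
    b_noise: float = 0.0
    snr: float = 15.0
    seed: int = 0
    base: str = "gaussian_field"

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if any(n % 2 for n in self.shape):
            raise ValueError("synthetic grids must have even lengths along every axis")
        if self.b_signal < 0 or self.b_noise < 0:
            raise ValueError("B-factors must be nonnegative")
        if not (self.snr > 0):
            raise ValueError("snr must be positive")
        if self.base not in ("gaussian_field", "phantom"):
            raise ValueError("base must be 'gaussian_field' or 'phantom'")

    def shells(self) -> ShellBinning:
        return build_shells(self.shape, self.voxel_size)


class MeasurementTruth(NamedTuple):
    """Ground truth bundle accompanying a synthetic measurement."""

    x: RealGrid
    lam2: RadialProfile
    sig2: RadialProfile


def bfactor_attenuation(shells: ShellBinning, b: float) -> RadialProfile:
    """Per-shell amplitude factor ``exp(-B s^2 / 4)``, 1 at shell 0."""
    if b < 0:
        raise ValueError("B-factor must be nonnegative")
    values = np.exp(-b * shells.frequencies**2 / 4.0)
    return RadialProfile(values, shells, kind="power")


def sample_field_from_profile(
    shells: ShellBinning, variance: np.ndarray, rng: np.random.Generator
) -> RealGrid:
    """Draw a real Gaussian field with per-shell Fourier variance ``variance``.

    Complex coefficients are drawn i.i.d. and Hermitian-symmetrized (the
    self-conjugate indices come out real with the correct variance); the DC
    component is zero (mean-zero model).  The per-index standard deviation is
    ``sqrt(variance[label])`` with the corner-extended shell label.
    """
    shape = shells.shape
    ext = extended_labels(shape)
    std = np.sqrt(np.asarray(variance, dtype=float))[ext]
    std.flat[0] = 0.0
    z = rng.normal(size=shape, scale=np.sqrt(0.5)) + 1j * rng.normal(size=shape, scale=np.sqrt(0.5))
    reflected = z[np.ix_(*[(-np.arange(n)) % n for n in shape])]
    coeff = std * (z + np.conj(reflected)) / np.sqrt(2.0)
    values = np.fft.ifftn(coeff, norm="ortho").real
    return RealGrid(values, shells.voxel_size)


def _profiles(spec: SyntheticSpec) -> tuple[ShellBinning, np.ndarray, np.ndarray]:
    """Exact lambda^2 and sigma^2 profiles (unit peak signal, snr-scaled noise)."""
    shells = spec.shells()
    lam2 = bfactor_attenuation(shells, spec.b_signal).values ** 2
    sig2 = bfactor_attenuation(shells, spec.b_noise).values ** 2
    ext = extended_labels(spec.shape)
    lam_tot = lam2[ext]
    sig_tot = sig2[ext]
    lam_sum = lam_tot.sum() - lam_tot.flat[0]
    sig_sum = sig_tot.sum() - sig_tot.flat[0]
    sig2 = sig2 * (lam_sum / (spec.snr * sig_sum))
    return shells, lam2, sig2


def sample_signal(spec: SyntheticSpec) -> tuple[RealGrid, RadialProfile]:
    """Draw the clean signal and return it with its exact lambda^2 profile."""
    shells, lam2, _ = _profiles(spec)
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    if spec.base == "phantom":
        x = phantom(spec.shape, spec.voxel_size)
        from .fourier import radial_power_spectrum

        lam2 = radial_power_spectrum(
            RealGrid(x.values - x.values.mean(), x.voxel_size), shells
        ).values
    else:
        x = sample_field_from_profile(shells, lam2, rng)
    return x, RadialProfile(lam2, shells, kind="power")


def sample_measurement(spec: SyntheticSpec) -> tuple[RealGrid, MeasurementTruth]:
    """Draw ``y = x + eps`` and the ground-truth bundle for oracles."""
    shells, lam2, sig2 = _profiles(spec)
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    if spec.base == "phantom":
        x = phantom(spec.shape, spec.voxel_size)
        from .fourier import radial_power_spectrum

        lam2 = radial_power_spectrum(
            RealGrid(x.values - x.values.mean(), x.voxel_size), shells
        ).values
        sig2 = np.full_like(lam2, x.values.var() / spec.snr)
    else:
        x = sample_field_from_profile(shells, lam2, rng)
    eps = sample_field_from_profile(shells, sig2, rng)
    y = RealGrid(x.values + eps.values, spec.voxel_size)
    truth = MeasurementTruth(
        x,
        RadialProfile(lam2, shells, kind="power"),
        RadialProfile(sig2, shells, kind="noise_variance"),
    )
    return y, truth


def sample_measurement_pair(spec: SyntheticSpec) -> tuple[RealGrid, RealGrid, MeasurementTruth]:
    """Shared signal, two independent noise draws - the ground-truth FSC pair."""
    shells, lam2, sig2 = _profiles(spec)
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    x = sample_field_from_profile(shells, lam2, rng)
    e1 = sample_field_from_profile(shells, sig2, rng)
    e2 = sample_field_from_profile(shells, sig2, rng)
    truth = MeasurementTruth(
        x,
        RadialProfile(lam2, shells, kind="power"),
        RadialProfile(sig2, shells, kind="noise_variance"),
    )
    return (
        RealGrid(x.values + e1.values, spec.voxel_size),
        RealGrid(x.values + e2.values, spec.voxel_size),
        truth,
    )


def phantom(shape: tuple[int, ...], voxel_size: float) -> RealGrid:
    """Deterministic compact scene: soft-edged spheres and a ring.

    Features are confined to the central half of the box and have tanh
    edges, giving a rapidly decaying spectrum.  Identical across runs.
    """
    shape = tuple(int(n) for n in shape)
    if any(n % 2 for n in shape):
        raise ValueError("phantom requires even axis lengths")
    d = len(shape)
    axes = [np.arange(n) - n / 2 + 0.5 for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    n_min = min(shape)
    # (center fractions, radius fraction, density, is_ring)
    features = [
        ((0.0,) * d, 0.16, 1.0, False),
        ((0.15, -0.10) + (0.05,) * (d - 2), 0.07, 0.8, False),
        ((-0.18, 0.08) + (-0.10,) * (d - 2), 0.10, 0.6, True),
        ((0.05, 0.20) + (0.12,) * (d - 2), 0.05, 1.2, False),
    ]
    out = np.zeros(shape)
    edge = 1.5  # voxels
    for center, rfrac, density, ring in features:
        r = np.sqrt(sum((g - c * n_min) ** 2 for g, c in zip(grids, center[:d])))
        radius = rfrac * n_min
        body = 0.5 * (1.0 - np.tanh((r - radius) / edge))
        if ring:
            body = body - 0.5 * (1.0 - np.tanh((r - 0.6 * radius) / edge))
        out += density * body
    return RealGrid(out, voxel_size)


def smooth_radial_field(
    shape: tuple[int, ...], voxel_size: float, fourier_width: float = 4.0
) -> RealGrid:
    """Deterministic band-limited field with an exactly radial spectrum.

    Coefficients are ``exp(-||k||^2 / (2 w^2))`` (real, Hermitian), defined
    directly in Fourier space so the spectrum has no box-truncation floor.
    Useful for phase-alignment diagnostics, where the shell-wise weighting
    must be constant for the unaligned curve to follow the Bessel J0 form.
    """
    from .fourier import frequency_radii

    rad = frequency_radii(shape)
    coeff = np.exp(-(rad**2) / (2.0 * fourier_width**2))
    values = np.fft.ifftn(coeff, norm="ortho").real
    return RealGrid(values, voxel_size)
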