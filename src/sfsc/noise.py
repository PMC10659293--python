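"""Noise spectrum estimation from signal-free regions, whitening and the
direct power-spectrum SSNR estimator.

The noise is modeled as mean-zero Gaussian with a diagonal Fourier
covariance constant on shells, so a single radial profile sigma^2(r)
describes it.  Two ad hoc estimators are provided: the spherically averaged
power spectrum of the region outside a sphere enclosing the structure
(single-particle maps), and of a slab above the region of interest
(tomograms)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .fourier import (
    RealGrid,
    RadialProfile,
    ShellBinning,
    build_shells,
    extended_labels,
    forward_transform,
    inverse_transform,
    FourierGrid,
    radial_power_spectrum,
)

logger = logging.getLogger(__name__)


@dataclass
class NoiseModel:
    """Per-shell noise variance on the parent grid's shells."""

    sigma2: RadialProfile
    method: str  # sphere_complement | slab | known
    region_spec: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.sigma2.values <= 0):
            raise ValueError("noise variance must be strictly positive at every shell")

    @classmethod
    def known(cls, sigma2: RadialProfile) -> "NoiseModel":
        return cls(sigma2, "known", {})


def estimate_noise_sphere_complement(g: RealGrid, radius: float) -> NoiseModel:
    """Noise spectrum from the region outside a centered sphere of ``radius`` A.

    Voxels inside the sphere are zeroed and the radial power spectrum of the
    masked grid is rescaled by (total voxels / outside voxels) to compensate
    the power removed with the masked fraction."""
    centers = [n // 2 for n in g.shape]
    coords = np.meshgrid(*[(np.arange(n) - c) * g.voxel_size for n, c in zip(g.shape, centers)],
                         indexing="ij")
    dist = np.sqrt(sum(c * c for c in coords))
    outside = dist > radius
    n_out = int(outside.sum())
    if n_out < 0.05 * g.values.size:
        raise ValueError(
            f"sphere of radius {radius} A leaves only {n_out} of {g.values.size} voxels "
            f"outside (< 5%); shrink the radius"
        )
    masked = RealGrid(np.where(outside, g.values, 0.0), g.voxel_size)
    shells = build_shells(g.shape, g.voxel_size)
    ps = radial_power_spectrum(masked, shells)
    sigma2 = ps.values * (g.values.size / n_out)
    sigma2 = _floor_guard(sigma2)
    return NoiseModel(
        RadialProfile(sigma2, shells, kind="noise_variance"),
        "sphere_complement",
        {"radius_angstrom": float(radius)},
    )


def estimate_noise_slab(g: RealGrid, axis: int, lo: int, hi: int) -> NoiseModel:
    """Noise spectrum from the slab ``lo:hi`` along ``axis``.

    The slab power spectrum is accumulated in bins of physical frequency
    (the slab is thinner than the parent, so raw index shells would mix
    physically different frequencies) and transferred to the parent shells by
    piecewise-linear interpolation in frequency."""
    n = g.shape[axis]
    if not (0 <= lo < hi <= n):
        raise ValueError(f"invalid slab [{lo}, {hi}) along axis {axis} of length {n}")
    sl = [slice(None)] * g.ndim
    sl[axis] = slice(lo, hi)
    slab = g.values[tuple(sl)]
    slab_shape = slab.shape
    # Hann taper along the cut axis: the hard slab edge would leak low-frequency
    # power into the spectral tail through sinc^2 sidelobes
    win = np.hanning(slab_shape[axis] + 2)[1:-1] if slab_shape[axis] > 1 else np.ones(1)
    reshape = [1] * slab.ndim
    reshape[axis] = slab_shape[axis]
    slab = slab * win.reshape(reshape)
    f = np.fft.fftn(slab, norm="ortho") / np.sqrt(np.mean(win**2))
    # physical frequency of every slab Fourier index
    grids = np.meshgrid(
        *[np.fft.fftfreq(m) / g.voxel_size for m in slab_shape], indexing="ij"
    )
    s = np.sqrt(sum(a * a for a in grids))
    ds = 1.0 / (min(slab_shape) * g.voxel_size)
    labels = np.rint(s / ds).astype(np.int64)
    nyq = 1.0 / (2.0 * g.voxel_size)
    keep = s <= nyq * (1 + 1e-9)
    nbins = int(labels[keep].max()) + 1
    power = np.bincount(labels[keep], weights=np.abs(f[keep]) ** 2, minlength=nbins)
    counts = np.bincount(labels[keep], minlength=nbins)
    with np.errstate(invalid="ignore"):
        prof = np.where(counts > 0, power / np.maximum(counts, 1), np.nan)
    freqs = np.arange(nbins) * ds
    good = np.isfinite(prof)
    shells = build_shells(g.shape, g.voxel_size)
    sigma2 = np.interp(shells.frequencies, freqs[good], prof[good])
    sigma2 = _floor_guard(sigma2)
    return NoiseModel(
        RadialProfile(sigma2, shells, kind="noise_variance"),
        "slab",
        {"axis": int(axis), "lo": int(lo), "hi": int(hi)},
    )


def _floor_guard(sigma2: np.ndarray) -> np.ndarray:
    floor = 1e-12 * np.max(sigma2)
    if np.any(sigma2 < floor):
        logger.warning("noise profile touched the positivity floor at %d shells",
                       int(np.sum(sigma2 < floor)))
    return np.maximum(sigma2, floor)


def whiten(g: RealGrid, nm: NoiseModel) -> RealGrid:
    """Divide every Fourier coefficient by sqrt(sigma^2) of its shell.

    The whitening is radial, hence Hermitian-symmetric: the output is real.
    Corner coefficients beyond the inscribed ball use the outermost shell's
    variance.  After whitening, noise drawn from ``nm`` has a flat radial
    power spectrum ~ 1 and the per-shell SSNR is unchanged."""
    if nm.sigma2.shells.shape != g.shape:
        raise ValueError("noise model was estimated on a different grid shape")
    ext = extended_labels(g.shape)
    w = np.sqrt(nm.sigma2.values)[ext]
    f = forward_transform(g)
    return inverse_transform(FourierGrid(f.coefficients / w, g.voxel_size))


def unwhiten(g: RealGrid, nm: NoiseModel) -> RealGrid:
    """Inverse of :func:`whiten` (multiply back by sqrt(sigma^2))."""
    ext = extended_labels(g.shape)
    w = np.sqrt(nm.sigma2.values)[ext]
    f = forward_transform(g)
    return inverse_transform(FourierGrid(f.coefficients * w, g.voxel_size))


def ssnr_direct(power: RadialProfile, nm: NoiseModel) -> RadialProfile:
    """SSNR as noise-subtracted power over noise: max(PS - s2, 0) / s2.

    A direct alternative to the FSC route whenever the noise spectrum is
    known or estimated; in expectation equal to lambda^2/sigma^2."""
    if power.shells.shape != nm.sigma2.shells.shape:
        raise ValueError("power and noise profiles live on different shell binnings")
    s2 = nm.sigma2.values
    values = np.maximum(power.values - s2, 0.0) / s2
    return RadialProfile(values, power.shells, kind="ssnr")


def noise_model_to_json(nm: NoiseModel) -> dict:
    return {
        "method": nm.method,
        "region_spec": nm.region_spec,
        "shells": [
            {"shell": int(r), "frequency_inv_angstrom": float(f), "sigma2": float(v)}
            for r, (f, v) in enumerate(zip(nm.sigma2.shells.frequencies, nm.sigma2.values))
        ],
    }
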