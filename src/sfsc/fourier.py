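"""Discrete Fourier conventions, radial shell binning and spectral profiles.

All transforms in this package use the unitary (``norm="ortho"``) DFT, so
Parseval's identity holds without extra factors and a white-noise field of
real-space variance 1 has a flat radial power spectrum equal to 1.

Fourier indices are the centered signed integers ``k in [-n/2, n/2)`` per
axis.  Radial shells partition the indices of the inscribed Nyquist ball
``||k|| <= min(shape)/2``; indices in the "corners" of the Fourier cube
beyond that ball are excluded from shells (those shells would be incomplete
and anisotropic).  Shell ``r`` sits at physical frequency
``r / (min(shape) * voxel_size)`` in 1/Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import resample


@dataclass
class RealGrid:
    """A real scalar field on a d-dimensional lattice (d in 1..3).

    Parameters
    ----------
    values : ndarray
        Real field values; any float dtype, stored as float64.
    voxel_size : float
        Physical sampling interval in Angstrom per voxel, uniform across axes.
    """

    values: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (1, 2, 3):
            raise ValueError(f"grids must be 1-, 2- or 3-dimensional, got {self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite values (NaN or Inf)")
        if not (self.voxel_size > 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim


@dataclass
class FourierGrid:
    """Unitary DFT coefficients of a :class:`RealGrid` (same shape)."""

    coefficients: np.ndarray
    voxel_size: float
    normalization: str = "unitary"

    @property
    def shape(self) -> tuple[int, ...]:
        return self.coefficients.shape

    @property
    def ndim(self) -> int:
        return self.coefficients.ndim


@dataclass
class ShellBinning:
    """Partition of Fourier indices into radial shells.

    ``shell_of`` holds the shell label of every index in unshifted (numpy
    fft) layout, with ``-1`` marking corner indices beyond the inscribed
    Nyquist ball.  ``counts[r]`` is the number of indices in shell ``r`` and
    ``frequencies[r]`` its physical frequency in 1/Angstrom.
    """

    shell_of: np.ndarray
    counts: np.ndarray
    frequencies: np.ndarray
    shape: tuple[int, ...]
    voxel_size: float

    @property
    def n_shells(self) -> int:
        return len(self.counts)

    @property
    def max_label(self) -> int:
        return self.n_shells - 1


@dataclass
class RadialProfile:
    """One real value per shell (power, noise variance, SSNR or gain)."""

    values: np.ndarray
    shells: ShellBinning
    kind: str = "power"

    _KINDS = ("power", "noise_variance", "ssnr", "correlation_gain")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if len(self.values) != self.shells.n_shells:
            raise ValueError("profile length does not match the number of shells")
        if self.kind in ("power", "noise_variance") and np.any(self.values < 0):
            raise ValueError(f"{self.kind} profile must be nonnegative")


def integer_frequencies(shape: Sequence[int]) -> list[np.ndarray]:
    """Centered signed integer frequency coordinates per axis, fft layout."""
    return list(np.meshgrid(*[np.fft.fftfreq(n) * n for n in shape], indexing="ij"))


def frequency_radii(shape: Sequence[int]) -> np.ndarray:
    """Euclidean norm of the integer frequency multi-index, fft layout."""
    grids = integer_frequencies(shape)
    return np.sqrt(sum(g * g for g in grids))


def extended_labels(shape: Sequence[int]) -> np.ndarray:
    """Shell labels extended to the whole Fourier cube.

    Corner indices beyond the inscribed Nyquist ball receive the label of the
    outermost shell ``R = min(shape)//2``.  Used wherever a radial profile
    must act on every coefficient (synthesis, whitening, shell-wise gains);
    radial statistics themselves are always restricted to the ball.
    """
    rad = frequency_radii(shape)
    return np.minimum(np.rint(rad).astype(np.int64), min(shape) // 2)


def forward_transform(g: RealGrid) -> FourierGrid:
    """Unitary forward DFT of a real grid.

    Parseval's identity holds: ``sum |coefficients|^2 == sum values^2``.
    """
    return FourierGrid(np.fft.fftn(g.values, norm="ortho"), voxel_size=g.voxel_size)


def inverse_transform(f: FourierGrid) -> RealGrid:
    """Unitary inverse DFT; imaginary residue of Hermitian input is dropped."""
    values = np.fft.ifftn(f.coefficients, norm="ortho")
    return RealGrid(values.real, voxel_size=f.voxel_size)


def build_shells(shape: Sequence[int], voxel_size: float) -> ShellBinning:
    """Bin Fourier indices into radial shells ``r = round(||k||)``.

    Indices with ``||k|| > min(shape)/2`` (the corners of the Fourier cube)
    are excluded.  Shell ``r`` is reported at frequency
    ``r / (min(shape) * voxel_size)``.
    """
    shape = tuple(int(n) for n in shape)
    if any(n < 2 for n in shape):
        raise ValueError(f"all axis lengths must be >= 2, got {shape}")
    if not (voxel_size > 0):
        raise ValueError("voxel_size must be positive")
    rad = frequency_radii(shape)
    nyquist = min(shape) / 2
    labels = np.rint(rad).astype(np.int64)
    labels[rad > nyquist] = -1
    max_label = min(shape) // 2
    counts = np.bincount(labels[labels >= 0].ravel(), minlength=max_label + 1)
    frequencies = np.arange(max_label + 1) / (min(shape) * voxel_size)
    return ShellBinning(labels, counts, frequencies, shape, voxel_size)


def shell_sum(shells: ShellBinning, values: np.ndarray) -> np.ndarray:
    """Sum ``values`` over each shell (corner indices ignored)."""
    mask = shells.shell_of >= 0
    return np.bincount(
        shells.shell_of[mask].ravel(),
        weights=np.asarray(values)[mask].ravel(),
        minlength=shells.n_shells,
    )


def radial_power_spectrum(g: RealGrid | FourierGrid, shells: ShellBinning) -> RadialProfile:
    """Spherically averaged power spectrum: mean of ``|y_hat[k]|^2`` per shell.

    The mean (rather than the sum) over the shell makes unit-variance white
    noise flat at 1 under the unitary convention.
    """
    f = g if isinstance(g, FourierGrid) else forward_transform(g)
    if f.shape != shells.shape:
        raise ValueError(f"grid shape {f.shape} does not match shell binning shape {shells.shape}")
    power = shell_sum(shells, np.abs(f.coefficients) ** 2)
    with np.errstate(invalid="ignore"):
        mean = np.where(shells.counts > 0, power / np.maximum(shells.counts, 1), 0.0)
    return RadialProfile(mean, shells, kind="power")


def zero_pad_upsample(g: RealGrid, factor: int = 2) -> RealGrid:
    """Band-limited upsampling by zero-padding in Fourier space.

    Real-space values at the original sample positions are preserved; the
    newly created frequencies above the original Nyquist carry (essentially)
    zero power.  The even-length Nyquist bin is split symmetrically between
    ``+N/2`` and ``-N/2`` to keep the output real, the standard Fourier
    resampling convention.
    """
    factor = int(factor)
    if factor < 2:
        raise ValueError(f"upsampling factor must be >= 2, got {factor}")
    out = g.values
    for ax in range(g.ndim):
        out = resample(out, factor * g.shape[ax], axis=ax)
    return RealGrid(out, voxel_size=g.voxel_size / factor)


def decimate(g: RealGrid, factor: int = 2) -> RealGrid:
    """Keep every ``factor``-th sample along every axis (inverse of upsampling
    for band-limited input)."""
    sl = tuple(slice(0, None, factor) for _ in range(g.ndim))
    return RealGrid(g.values[sl], voxel_size=g.voxel_size * factor)


def lowpass(g: RealGrid, cutoff: float) -> RealGrid:
    """Hard low-pass at a resolution cutoff in Angstrom.

    Fourier coefficients at physical frequencies above ``1/cutoff`` are set
    to zero, including corner indices beyond the inscribed Nyquist ball.
    """
    nyquist_resolution = 2.0 * g.voxel_size
    if cutoff < nyquist_resolution:
        raise ValueError(
            f"cutoff {cutoff} A is finer than the Nyquist limit "
            f"{nyquist_resolution} A (= 2 * voxel size)"
        )
    f = forward_transform(g)
    rad = frequency_radii(g.shape)
    keep_radius = min(g.shape) * g.voxel_size / cutoff
    coeff = np.where(rad <= keep_radius + 1e-9, f.coefficients, 0.0)
    return inverse_transform(FourierGrid(coeff, g.voxel_size))
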