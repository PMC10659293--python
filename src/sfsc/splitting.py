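"""Even/odd decimation of a measurement and phase-shift alignment.

A measurement split into even- and odd-index samples along one axis yields
two half-size grids of the same underlying signal.  In Fourier space the two
halves are related to the parent transform by the standard decimation
identities, and the odd half carries an extra half-voxel translation phase
``exp(-2*pi*i*k/N)`` which must be compensated before correlating them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import FourierGrid, RealGrid, forward_transform


@dataclass
class SplitPair:
    """The two decimated halves of a parent measurement.

    ``scheme`` is ``"axis"`` (even/odd along one axis, the default SFSC
    scheme) or ``"checkerboard"`` (simultaneous parity on every axis,
    retained as a comparison mode).
    """

    first: RealGrid
    second: RealGrid
    split_axes: tuple[int, ...]
    parent_shape: tuple[int, ...]
    scheme: str


def _odd_length_error(axis: int, n: int) -> ValueError:
    return ValueError(
        f"axis {axis} has odd length {n}; even/odd splitting needs an even "
        f"length - crop the grid by one voxel along that axis first "
        f"(cropping is left to the caller, it changes the frequency axis)"
    )


def split_even_odd(g: RealGrid, axis: int) -> SplitPair:
    """Split ``g`` into even- and odd-index samples along ``axis``.

    ``first[n] = g[2n]`` and ``second[n] = g[2n+1]`` along the split axis;
    other axes are untouched.  The stored voxel size doubles (the sampling
    interval along the split axis; see the package notes on the frequency
    convention for the unsplit axes).
    """
    n = g.shape[axis]
    if n % 2:
        raise _odd_length_error(axis, n)
    even = [slice(None)] * g.ndim
    odd = [slice(None)] * g.ndim
    even[axis] = slice(0, None, 2)
    odd[axis] = slice(1, None, 2)
    first = RealGrid(g.values[tuple(even)], voxel_size=g.voxel_size * 2)
    second = RealGrid(g.values[tuple(odd)], voxel_size=g.voxel_size * 2)
    return SplitPair(first, second, (axis,), g.shape, "axis")


def interleave(pair: SplitPair) -> RealGrid:
    """Reconstruct the parent of an axis-scheme pair exactly."""
    if pair.scheme != "axis":
        raise ValueError("only axis-scheme pairs can be interleaved back")
    (axis,) = pair.split_axes
    out = np.empty(pair.parent_shape, dtype=np.float64)
    even = [slice(None)] * out.ndim
    odd = [slice(None)] * out.ndim
    even[axis] = slice(0, None, 2)
    odd[axis] = slice(1, None, 2)
    out[tuple(even)] = pair.first.values
    out[tuple(odd)] = pair.second.values
    return RealGrid(out, voxel_size=pair.first.voxel_size / 2)


def split_checkerboard(g: RealGrid) -> SplitPair:
    """Decimate keeping all-even-index and all-odd-index samples.

    Each half holds ``parent_size / 2^d`` samples; the remaining mixed-parity
    classes are discarded.  Kept for comparison with the per-axis scheme: it
    inflates the SFSC noise variance by ``2^d`` instead of 2.
    """
    if g.ndim < 2:
        raise ValueError("checkerboard splitting needs d >= 2 (identical to split_even_odd in 1-D)")
    for ax, n in enumerate(g.shape):
        if n % 2:
            raise _odd_length_error(ax, n)
    ee = tuple(slice(0, None, 2) for _ in range(g.ndim))
    oo = tuple(slice(1, None, 2) for _ in range(g.ndim))
    first = RealGrid(g.values[ee], voxel_size=g.voxel_size * 2)
    second = RealGrid(g.values[oo], voxel_size=g.voxel_size * 2)
    return SplitPair(first, second, tuple(range(g.ndim)), g.shape, "checkerboard")


def _axis_phase(shape: tuple[int, ...], axis: int, parent_length: int) -> np.ndarray:
    """Half-voxel alignment phase exp(-2*pi*i*k/N) along ``axis``.

    ``k`` is the centered signed frequency index of the decimated grid and
    ``N`` the parent length: odd samples sit one parent voxel (half a
    decimated voxel) after the even ones.
    """
    k = np.fft.fftfreq(shape[axis]) * shape[axis]
    phase = np.exp(-2j * np.pi * k / parent_length)
    reshape = [1] * len(shape)
    reshape[axis] = shape[axis]
    return phase.reshape(reshape)


def phase_align(pair: SplitPair) -> tuple[FourierGrid, FourierGrid]:
    """Forward transforms of the pair with the odd half phase-corrected.

    Multiplies the second (odd) half's coefficients by ``exp(-2*pi*i*k/N)``
    along the split axis, compensating the ``omega_N^k`` factor of the
    decimation identity so that a noiseless smooth signal correlates to ~1.
    """
    if pair.scheme != "axis":
        raise ValueError("phase alignment is defined per axis; checkerboard pairs are not supported")
    (axis,) = pair.split_axes
    f1 = forward_transform(pair.first)
    f2 = forward_transform(pair.second)
    f2.coefficients = f2.coefficients * _axis_phase(
        pair.second.shape, axis, pair.parent_shape[axis]
    )
    return f1, f2


def checkerboard_transforms(pair: SplitPair) -> tuple[FourierGrid, FourierGrid]:
    """Transforms of a checkerboard pair with the diagonal phase alignment.

    The all-odd half is translated by one parent voxel along *every* axis,
    so the alignment phase is ``exp(-2*pi*i * sum_a k_a / N_a)``.
    """
    if pair.scheme != "checkerboard":
        raise ValueError("expected a checkerboard pair")
    f1 = forward_transform(pair.first)
    f2 = forward_transform(pair.second)
    for axis in pair.split_axes:
        f2.coefficients = f2.coefficients * _axis_phase(
            pair.second.shape, axis, pair.parent_shape[axis]
        )
    return f1, f2
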