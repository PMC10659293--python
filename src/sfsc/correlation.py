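"""FSC and self-FSC estimators, closed-form expectations and corrections.

The self Fourier shell correlation (SFSC) estimates the FSC of a single
noisy measurement from its even/odd-decimated halves.  Under the Gaussian
model ``y = x + eps`` with diagonal Fourier covariances that are constant on
shells (signal variance ``lambda^2(r)``, noise variance ``sigma^2(r)``), the
expectation-ratio analogue of the SFSC is, per aliasing pair,

    ESFSC = (l2[k] - l2[k'] + s2[k] - s2[k'])
          / (l2[k] + l2[k'] + s2[k] + s2[k']),        k' = k + N/2 e_axis,

which for white noise and a rapidly decaying signal spectrum reduces to
``l2/(l2 + 2 s2)`` - the FSC with the noise variance doubled.  The variance
correction ``2c/(1+c)`` maps that back onto the EFSC ``l2/(l2 + s2)`` scale.
For slowly decaying spectra, upsampling a whitened measurement by Fourier
zero-padding and subtracting the known noise term from the correlation
numerator targets the EFSC directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .fourier import (
    FourierGrid,
    RealGrid,
    ShellBinning,
    RadialProfile,
    build_shells,
    extended_labels,
    forward_transform,
    integer_frequencies,
    shell_sum,
    zero_pad_upsample,
)
from .splitting import checkerboard_transforms, phase_align, split_checkerboard, split_even_odd

_SFSC_PROVENANCES = ("sfsc_axis", "sfsc_mean", "sfsc_checkerboard", "esfsc_closed_form")


@dataclass
class CorrelationCurve:
    """Per-shell correlation values with their frequency axis.

    Undefined shells (zero norm in either half) are carried as NaN, never as
    zero.  ``corrected`` records whether the ``2c/(1+c)`` variance rescaling
    has been applied (or, for the upsampled estimator, that the curve targets
    the EFSC directly).
    """

    values: np.ndarray
    shells: ShellBinning
    frequencies: np.ndarray
    counts: np.ndarray
    corrected: bool
    provenance: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_shells(self) -> int:
        return len(self.values)


def _fsc_from_transforms(f1: FourierGrid, f2: FourierGrid, shells: ShellBinning) -> np.ndarray:
    num = shell_sum(shells, (f1.coefficients * np.conj(f2.coefficients)).real)
    d1 = shell_sum(shells, np.abs(f1.coefficients) ** 2)
    d2 = shell_sum(shells, np.abs(f2.coefficients) ** 2)
    den = np.sqrt(d1 * d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(values, -1.0, 1.0)


def fsc(g1: RealGrid, g2: RealGrid, shells: ShellBinning | None = None) -> CorrelationCurve:
    """Standard Fourier shell correlation of two measurements.

    Per shell ``Re<y1_hat, y2_hat> / (||y1_hat|| * ||y2_hat||)``; shells with
    a vanishing norm are flagged undefined.
    """
    if g1.shape != g2.shape:
        raise ValueError(f"shape mismatch: {g1.shape} vs {g2.shape}")
    if g1.voxel_size != g2.voxel_size:
        raise ValueError("voxel size mismatch between the two grids")
    if shells is None:
        shells = build_shells(g1.shape, g1.voxel_size)
    if shells.shape != g1.shape:
        raise ValueError("shell binning was built for a different shape")
    values = _fsc_from_transforms(forward_transform(g1), forward_transform(g2), shells)
    return CorrelationCurve(values, shells, shells.frequencies, shells.counts, False, "fsc")


def _sfsc_one_axis(g: RealGrid, axis: int) -> CorrelationCurve:
    pair = split_even_odd(g, axis)
    f1, f2 = phase_align(pair)
    shells = build_shells(pair.first.shape, pair.first.voxel_size)
    values = _fsc_from_transforms(f1, f2, shells)
    return CorrelationCurve(values, shells, shells.frequencies, shells.counts, False, "sfsc_axis")


def _average_axis_curves(curves: list[CorrelationCurve], provenance: str) -> CorrelationCurve:
    n = min(c.n_shells for c in curves)
    stacked = np.array([c.values[:n] for c in curves])
    with np.errstate(invalid="ignore"):
        mean = np.where(np.any(np.isfinite(stacked), axis=0), np.nanmean(stacked, axis=0), np.nan)
    ref = curves[0]
    return CorrelationCurve(
        mean, ref.shells, ref.frequencies[:n], ref.counts[:n], False, provenance
    )


def sfsc(g: RealGrid, return_per_axis: bool = False):
    """Self-FSC: per-axis even/odd split, phase alignment, FSC, axis average.

    The returned curve lives on the decimated grid's shells, i.e. it covers
    the lower half of the parent frequency range at the parent's frequency
    spacing.  ``corrected`` is False; apply :func:`variance_correction` to
    move onto the EFSC scale.
    """
    for ax, n in enumerate(g.shape):
        if n % 2:
            raise ValueError(
                f"axis {ax} has odd length {n}; crop by one voxel before computing the SFSC"
            )
    per_axis = [_sfsc_one_axis(g, ax) for ax in range(g.ndim)]
    mean = _average_axis_curves(per_axis, "sfsc_mean")
    if return_per_axis:
        return mean, per_axis
    return mean


def sfsc_checkerboard(g: RealGrid) -> CorrelationCurve:
    """Self-FSC from the checkerboard (all-axes parity) decimation.

    Comparison mode only: its noise variance inflation is ``2^d`` instead of
    the per-axis scheme's 2.
    """
    pair = split_checkerboard(g)
    f1, f2 = checkerboard_transforms(pair)
    shells = build_shells(pair.first.shape, pair.first.voxel_size)
    values = _fsc_from_transforms(f1, f2, shells)
    return CorrelationCurve(
        values, shells, shells.frequencies, shells.counts, False, "sfsc_checkerboard"
    )


def efsc_closed_form(lam2: RadialProfile, sig2: RadialProfile) -> CorrelationCurve:
    """Deterministic expectation FSC: ``lambda^2 / (lambda^2 + sigma^2)``."""
    if lam2.shells is not sig2.shells and lam2.shells.shape != sig2.shells.shape:
        raise ValueError("signal and noise profiles must share their shell binning")
    den = lam2.values + sig2.values
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, lam2.values / np.where(den > 0, den, 1.0), np.nan)
    sh = lam2.shells
    return CorrelationCurve(values, sh, sh.frequencies, sh.counts, True, "efsc_closed_form")


def esfsc_closed_form(
    lam2: RadialProfile, sig2: RadialProfile, axis: int | None = None
) -> CorrelationCurve:
    """Expectation of the (uncorrected) SFSC under the Gaussian shell model.

    Exact per-index aliasing-partner sum over each decimated shell: for the
    split along ``axis`` the partner of multi-index ``k`` is
    ``k + (N/2) e_axis`` (in d >= 2 its radius varies within a shell, so the
    printed 1-D per-shell formula is recovered only for d = 1).  Profiles are
    evaluated on the full Fourier cube with the corner extension used by the
    synthetic sampler, making this the exact oracle for sampled fields.
    With ``axis=None`` the per-axis expectations are averaged as in
    :func:`sfsc`.
    """
    shape = lam2.shells.shape
    if sig2.shells.shape != shape:
        raise ValueError("signal and noise profiles must share their shell binning")
    ext = extended_labels(shape)
    t = (lam2.values + sig2.values)[ext]
    t.flat[0] = 0.0  # mean-zero model: no DC component
    axes = range(len(shape)) if axis is None else [axis]
    curves = []
    for ax in axes:
        t_partner = np.roll(t, shape[ax] // 2, axis=ax)
        dshape = list(shape)
        dshape[ax] //= 2
        dshells = build_shells(tuple(dshape), lam2.shells.voxel_size * 2)
        # decimated Fourier index -> parent index with the same centered k
        idx = integer_frequencies(tuple(dshape))
        parent_idx = tuple(a.astype(np.int64) % shape[i] for i, a in enumerate(idx))
        num = shell_sum(dshells, t[parent_idx] - t_partner[parent_idx])
        den = shell_sum(dshells, t[parent_idx] + t_partner[parent_idx])
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        curves.append(
            CorrelationCurve(
                values, dshells, dshells.frequencies, dshells.counts, False, "esfsc_closed_form"
            )
        )
    if len(curves) == 1:
        return curves[0]
    out = _average_axis_curves(curves, "esfsc_closed_form")
    return out


def variance_correction(c: CorrelationCurve) -> CorrelationCurve:
    """Map an SFSC-scale curve onto the EFSC scale: ``v -> 2v/(1+v)``.

    Compensates the doubling of the noise variance induced by decimation
    (white noise, rapidly decaying signal).  Shells at the ``v = -1`` pole
    become undefined; applying the correction twice is an error.
    """
    if c.provenance not in _SFSC_PROVENANCES:
        raise ValueError(f"variance correction applies to SFSC-type curves, not {c.provenance!r}")
    if c.corrected:
        raise ValueError("variance correction already applied to this curve")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(
            np.isclose(c.values, -1.0), np.nan, 2.0 * c.values / (1.0 + c.values)
        )
    return replace(c, values=values, corrected=True)


def sfsc_upsampled(
    g_whitened: RealGrid, sigma2: float = 1.0, gamma: float | None = None
) -> CorrelationCurve:
    """Self-FSC of a 2x Fourier-upsampled whitened measurement with noise
    subtraction in the numerator.

    After zero-padding, the aliasing partner of every retained frequency is
    (deterministically) zero, so the decimated halves are identical up to the
    phase shift and correlate to 1; subtracting the known per-coefficient
    noise term ``gamma`` from the numerator turns the ratio into a direct
    estimate of the EFSC ``lambda^2/(lambda^2 + sigma^2)``.

    The caller asserts the input is whitened (per-coefficient noise variance
    ``sigma2``, default 1, in the unitary convention).  In that convention,
    with value-preserving upsampling, the noise term per retained coefficient
    is ``2^(d-1) * sigma2``, which is the default ``gamma``.  The returned
    curve covers the full original frequency range (shells above the original
    Nyquist carry only padding and are not produced) and is already on the
    EFSC scale (``corrected=True``).
    """
    d = g_whitened.ndim
    if gamma is None:
        gamma = 2.0 ** (d - 1) * sigma2
    up = zero_pad_upsample(g_whitened, 2)
    curves = []
    for ax in range(d):
        pair = split_even_odd(up, ax)
        f1, f2 = phase_align(pair)
        shells = build_shells(pair.first.shape, pair.first.voxel_size)
        num = shell_sum(shells, (f1.coefficients * np.conj(f2.coefficients)).real)
        num = num - shells.counts * gamma
        d1 = shell_sum(shells, np.abs(f1.coefficients) ** 2)
        d2 = shell_sum(shells, np.abs(f2.coefficients) ** 2)
        den = np.sqrt(d1 * d2)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        values = np.clip(values, -1.0, 1.0)
        curves.append(
            CorrelationCurve(values, shells, shells.frequencies, shells.counts, False, "sfsc_axis")
        )
    out = _average_axis_curves(curves, "sfsc_upsampled")
    out.corrected = True
    return out


def fit_noise_inflation(
    mean_values: np.ndarray,
    lam2: np.ndarray,
    sig2: np.ndarray,
    mask: np.ndarray,
    bounds: tuple[float, float] = (0.5, 32.0),
) -> float:
    """Least-squares fit of ``c`` in ``mean SFSC ~= l2/(l2 + c*s2)`` per shell.

    ``lam2``/``sig2`` are the parent-grid per-coefficient variances at the
    decimated shell labels; ``mask`` selects the shells entering the fit
    (typically those satisfying the rapid-decay assumption).
    """
    mean_values = np.asarray(mean_values, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)[: len(mean_values)]
    sig2 = np.asarray(sig2, dtype=float)[: len(mean_values)]
    mask = np.asarray(mask, dtype=bool)[: len(mean_values)]

    def loss(c: float) -> float:
        model = lam2 / (lam2 + c * sig2)
        return float(np.sum((mean_values[mask] - model[mask]) ** 2))

    res = minimize_scalar(loss, bounds=bounds, method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# serialization

CURVE_COLUMNS = ["shell", "frequency_inv_angstrom", "resolution_angstrom", "value", "count", "defined"]


def curve_to_dataframe(c: CorrelationCurve):
    import pandas as pd

    with np.errstate(divide="ignore"):
        resolution = np.where(c.frequencies > 0, 1.0 / np.where(c.frequencies > 0, c.frequencies, 1.0), np.inf)
    return pd.DataFrame(
        {
            "shell": np.arange(c.n_shells),
            "frequency_inv_angstrom": c.frequencies,
            "resolution_angstrom": resolution,
            "value": c.values,
            "count": c.counts,
            "defined": c.defined,
        },
        columns=CURVE_COLUMNS,
    )


def write_curve_csv(c: CorrelationCurve, path: str | Path) -> None:
    curve_to_dataframe(c).to_csv(path, index=False)


def write_curve_json(c: CorrelationCurve, path: str | Path) -> None:
    payload = {
        "provenance": c.provenance,
        "corrected": bool(c.corrected),
        "voxel_size_angstrom": c.shells.voxel_size,
        "grid_shape": list(c.shells.shape),
        "shells": curve_to_dataframe(c).replace({np.nan: None}).to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
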