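"""Consumers of correlation curves: SSNR conversion, resolution estimation,
Wiener filtering and the preprocessing diagnostics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import CorrelationCurve
from .fourier import (
    FourierGrid,
    RadialProfile,
    RealGrid,
    build_shells,
    extended_labels,
    forward_transform,
    inverse_transform,
    lowpass,
    radial_power_spectrum,
)


@dataclass
class ResolutionResult:
    """Resolution at a threshold crossing of a correlation curve.

    ``status`` is ``"crossed"`` (interpolated crossing found), ``"never_below"``
    (curve stays above threshold; resolution is the Nyquist limit) or
    ``"below_at_start"`` (curve starts below threshold; undefined)."""

    resolution: float
    frequency: float
    threshold: float
    status: str


@dataclass
class WienerResult:
    filtered: RealGrid
    gain: RadialProfile
    source_curve: CorrelationCurve
    cutoff_used: float | None = None


@dataclass
class DiagnosticReport:
    """Flat-tail check of the radial power spectrum (preprocessing guide)."""

    cv_upper_half: float
    flat: bool
    decay_ratio: float
    recommendations: list[str] = field(default_factory=list)


def ssnr_from_fsc(c: CorrelationCurve) -> RadialProfile:
    """Invert the FSC-SSNR relation: ``SSNR = c/(1-c)``.

    Negative curve values clamp to SSNR 0; values at 1 map to infinity."""
    v = c.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ssnr = np.where(v >= 1.0, np.inf, np.maximum(v, 0.0) / (1.0 - np.minimum(v, 1.0 - 1e-300)))
    ssnr = np.where(np.isfinite(v), ssnr, np.nan)
    return RadialProfile(np.nan_to_num(ssnr, nan=0.0, posinf=np.inf), c.shells, kind="ssnr")


def resolution_at_threshold(c: CorrelationCurve, threshold: float = 1.0 / 7.0) -> ResolutionResult:
    """First downward crossing of ``threshold``, low to high frequency.

    Linear interpolation in frequency between the bracketing shells; the
    returned resolution is ``1/frequency`` in Angstrom."""
    mask = c.defined & (c.frequencies > 0)
    if mask.sum() < 2:
        raise ValueError("curve must be defined on at least two nonzero-frequency shells")
    freqs = c.frequencies[mask]
    vals = c.values[mask]
    if vals[0] < threshold:
        return ResolutionResult(np.nan, np.nan, threshold, "below_at_start")
    below = np.nonzero(vals < threshold)[0]
    if len(below) == 0:
        f = freqs[-1]
        return ResolutionResult(1.0 / f, f, threshold, "never_below")
    i = below[0]
    f0, f1 = freqs[i - 1], freqs[i]
    v0, v1 = vals[i - 1], vals[i]
    f = f0 + (v0 - threshold) / (v0 - v1) * (f1 - f0)
    return ResolutionResult(1.0 / f, f, threshold, "crossed")


def _gain_on_parent_shells(c: CorrelationCurve, parent_shells) -> np.ndarray:
    """Map curve values onto the parent shell frequencies.

    Exact where frequencies coincide (the decimated grid keeps the parent's
    frequency spacing); linear interpolation otherwise; zero beyond the
    curve's frequency range (no information there, assume pure noise)."""
    mask = c.defined
    if mask.sum() < 2:
        raise ValueError("correlation curve has fewer than two defined shells")
    return np.interp(
        parent_shells.frequencies, c.frequencies[mask], c.values[mask], left=c.values[mask][0], right=0.0
    )


def wiener_filter(
    g: RealGrid,
    c: CorrelationCurve,
    apply_cutoff: bool = False,
    require_corrected: bool = True,
) -> WienerResult:
    """Shell-wise Wiener filter driven by a correlation curve.

    The minimum-MSE gain ``SSNR/(1+SSNR)`` equals the EFSC, so the measurement
    is multiplied shell-wise by the (variance-corrected) SFSC clamped to
    [0, 1].  With ``apply_cutoff`` an additional hard low-pass is placed at
    the 1/7-threshold resolution of the curve."""
    if require_corrected and not c.corrected:
        raise ValueError(
            "Wiener gain expects an EFSC-scale curve; apply variance_correction first "
            "(or pass require_corrected=False to use the raw curve)"
        )
    parent_shells = build_shells(g.shape, g.voxel_size)
    gain_values = np.clip(_gain_on_parent_shells(c, parent_shells), 0.0, 1.0)
    ext = extended_labels(g.shape)
    f = forward_transform(g)
    gain_map = gain_values[ext]
    gain_map.flat[0] = 1.0  # the mean is not an estimation target; pass DC through
    filtered = inverse_transform(FourierGrid(f.coefficients * gain_map, g.voxel_size))
    cutoff = None
    if apply_cutoff:
        res = resolution_at_threshold(c)
        if res.status != "below_at_start" and np.isfinite(res.resolution):
            cutoff = max(res.resolution, 2.0 * g.voxel_size)
            filtered = lowpass(filtered, cutoff)
    gain = RadialProfile(gain_values, parent_shells, kind="correlation_gain")
    return WienerResult(filtered, gain, c, cutoff)


def diagnose(g: RealGrid, cv_threshold: float = 0.1, decay_threshold: float = 10.0) -> DiagnosticReport:
    """Check the flat-tail condition of the radial power spectrum.

    If the upper half of the spectrum is approximately constant
    (coefficient of variation below ``cv_threshold``) the white-noise
    assumption is plausible; otherwise whitening is recommended.  A flat
    spectrum with weak overall decay indicates a slowly decaying signal, for
    which the upsampled estimator is recommended."""
    shells = build_shells(g.shape, g.voxel_size)
    ps = radial_power_spectrum(g, shells).values
    half = len(ps) // 2
    # coarse count-weighted bins suppress the chi-square sampling noise of
    # individual shells (relative std ~ sqrt(2/n_r) per shell on one image)
    upper_idx = np.arange(half, len(ps))
    bins = np.array_split(upper_idx, 4)
    w = shells.counts
    binned = np.array([np.average(ps[b], weights=np.maximum(w[b], 1)) for b in bins if len(b)])
    cv = float(np.std(binned) / np.mean(binned)) if np.mean(binned) > 0 else np.inf
    upper = ps[half:]
    lower = ps[1:half]
    decay = float(np.mean(lower) / np.mean(upper)) if np.mean(upper) > 0 else np.inf
    flat = cv < cv_threshold
    recs = []
    if not flat:
        recs.append("whiten")
    elif decay < decay_threshold:
        recs.append("upsample")
    return DiagnosticReport(cv, flat, decay, recs)
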