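"""Minimal plotting helper for correlation curves and radial profiles."""

from __future__ import annotations

from .correlation import CorrelationCurve
from .fourier import RadialProfile


def plot_curve(curve: CorrelationCurve, ax=None, threshold: float | None = 1.0 / 7.0, **kwargs):
    """Plot a correlation curve against spatial frequency (1/Angstrom)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.frequencies, curve.values, label=curve.provenance, **kwargs)
    if threshold is not None:
        ax.axhline(threshold, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("spatial frequency (1/$\\mathrm{\\AA}$)")
    ax.set_ylabel("correlation")
    ax.set_ylim(-0.2, 1.05)
    ax.legend(frameon=False)
    return ax


def plot_profile(profile: RadialProfile, ax=None, log: bool = True, **kwargs):
    """Plot a radial profile (power spectrum, noise variance, SSNR)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.shells.frequencies, profile.values, label=profile.kind, **kwargs)
    if log:
        ax.set_yscale("log")
    ax.set_xlabel("spatial frequency (1/$\\mathrm{\\AA}$)")
    ax.set_ylabel(profile.kind)
    ax.legend(frameon=False)
    return ax
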