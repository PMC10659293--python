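"""FSC/SFSC estimators against brute-force and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sfsc import (
    RealGrid,
    RadialProfile,
    build_shells,
    efsc_closed_form,
    esfsc_closed_form,
    fsc,
    sfsc,
    sfsc_upsampled,
    smooth_radial_field,
    ssnr_from_fsc,
    variance_correction,
)
from sfsc.correlation import curve_to_dataframe, CURVE_COLUMNS
from sfsc.synthetic import sample_field_from_profile

from conftest import brute_force_shell_indices


def _profile(shells, values, kind="power"):
    return RadialProfile(np.asarray(values, dtype=float), shells, kind=kind)


class TestFsc:
    def test_identical_inputs_give_one_everywhere(self, random_grid):
        g = random_grid((16, 16))
        c = fsc(g, g)
        assert np.allclose(c.values[c.defined], 1.0, atol=1e-12)

    def test_independent_white_noise_averages_to_zero(self):
        shells = build_shells((16, 16), 1.0)
        acc = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            c = fsc(RealGrid(r.normal(size=(16, 16)), 1.0), RealGrid(r.normal(size=(16, 16)), 1.0))
            acc.append(c.values)
        mean = np.nanmean(acc, axis=0)
        bound = 3.0 / np.sqrt(shells.counts * 100)
        assert np.all(np.abs(mean[1:]) < bound[1 : len(mean)] + 0.02)

    def test_matches_brute_force_shell_loop(self, rng):
        a = rng.integers(-4, 5, size=(8, 8)).astype(float)
        b = rng.integers(-4, 5, size=(8, 8)).astype(float)
        c = fsc(RealGrid(a, 1.0), RealGrid(b, 1.0))
        fa = np.fft.fftn(a, norm="ortho")
        fb = np.fft.fftn(b, norm="ortho")
        for r, idxs in brute_force_shell_indices((8, 8)).items():
            num = sum((fa[i] * np.conj(fb[i])).real for i in idxs)
            den = np.sqrt(
                sum(abs(fa[i]) ** 2 for i in idxs) * sum(abs(fb[i]) ** 2 for i in idxs)
            )
            assert c.values[r] == pytest.approx(num / den, abs=1e-10)

    def test_shape_mismatch_rejected(self, random_grid):
        with pytest.raises(ValueError, match="mismatch"):
            fsc(random_grid((8, 8)), random_grid((8, 10)))


class TestSfsc:
    def test_noiseless_smooth_signal_correlates_to_one(self):
        g = smooth_radial_field((64, 64), 1.0, fourier_width=4.0)
        c = sfsc(g)
        assert c.provenance == "sfsc_mean" and not c.corrected
        assert np.all(c.values[1:-1] > 0.9)

    def test_pure_white_noise_averages_to_zero(self):
        """Full-cube white noise has a vanishing ESFSC numerator at every
        shell, so the per-shell Monte-Carlo mean must be ~0."""
        acc = []
        for seed in range(200):
            g = RealGrid(np.random.default_rng(seed).normal(size=(32, 32)), 1.0)
            acc.append(sfsc(g).values)
        acc = np.array(acc)
        mean = acc.mean(0)
        se = acc.std(0, ddof=1) / np.sqrt(len(acc))
        assert np.all(np.abs(mean[1:]) < 4 * se[1:])

    def test_monte_carlo_mean_matches_closed_form(self):
        """Per-shell MC mean of the SFSC agrees with the exact per-index
        expectation ratio on well-populated shells (the ratio estimator has
        O(1/n_r) bias on sparse shells, which are excluded)."""
        shape = (64, 64)
        shells = build_shells(shape, 0.5)
        s = shells.frequencies
        rng = np.random.default_rng(11)
        worst = []
        for _ in range(2):
            lam2 = np.exp(rng.uniform(0, 2)) * np.exp(-rng.uniform(20, 120) * s**2 / 2)
            sig2 = np.exp(rng.uniform(-1, 1)) * np.exp(-rng.uniform(0, 60) * s**2 / 2)
            orc = esfsc_closed_form(_profile(shells, lam2), _profile(shells, sig2))
            acc = []
            for seed in range(150):
                child = np.random.default_rng(1000 + seed)
                x = sample_field_from_profile(shells, lam2, child)
                e = sample_field_from_profile(shells, sig2, child)
                acc.append(sfsc(RealGrid(x.values + e.values, 0.5)).values)
            acc = np.array(acc)
            mean = acc.mean(0)
            se = acc.std(0, ddof=1) / np.sqrt(len(acc))
            sel = (orc.counts >= 30)[: len(mean)]
            sel[0] = sel[-1] = False
            z = (mean - orc.values[: len(mean)])[sel] / se[sel]
            worst.append(np.abs(z))
        worst = np.concatenate(worst)
        assert np.mean(worst <= 3.0) >= 0.9
        assert np.max(worst) < 5.0

    def test_odd_axis_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            sfsc(RealGrid(np.zeros((6, 7)), 1.0))


class TestClosedForms:
    def test_esfsc_reduces_to_doubled_noise_form(self):
        """With flat noise and no partner-shell signal the ESFSC is
        lambda^2/(lambda^2 + 2 sigma^2)."""
        shells = build_shells((64,), 1.0)
        lam2 = np.zeros(33)
        lam2[:16] = 5.0
        sig2 = np.full(33, 2.0)
        c = esfsc_closed_form(_profile(shells, lam2), _profile(shells, sig2))
        assert np.allclose(c.values[1:15], 5.0 / (5.0 + 2 * 2.0), atol=1e-12)

    def test_esfsc_half_for_signal_twice_flat_noise(self):
        shells = build_shells((64,), 1.0)
        lam2 = np.zeros(33)
        lam2[:16] = 2.0
        sig2 = np.full(33, 1.0)
        c = esfsc_closed_form(_profile(shells, lam2), _profile(shells, sig2))
        assert np.allclose(c.values[1:15], 0.5, atol=1e-12)

    def test_esfsc_zero_signal_is_zero(self):
        shells = build_shells((64,), 1.0)
        c = esfsc_closed_form(_profile(shells, np.zeros(33)), _profile(shells, np.ones(33)))
        assert np.allclose(c.values[1:], 0.0, atol=1e-12)

    def test_efsc_examples(self):
        shells = build_shells((16,), 1.0)
        ones = np.ones(9)
        c = efsc_closed_form(_profile(shells, ones), _profile(shells, ones))
        assert np.allclose(c.values, 0.5)
        c2 = efsc_closed_form(_profile(shells, ones), _profile(shells, np.zeros(9)))
        assert np.allclose(c2.values, 1.0)

    def test_ssnr_inversion_round_trip(self, rng):
        shells = build_shells((16,), 1.0)
        lam2 = rng.uniform(0.1, 5.0, size=9)
        sig2 = rng.uniform(0.1, 2.0, size=9)
        ssnr = ssnr_from_fsc(efsc_closed_form(_profile(shells, lam2), _profile(shells, sig2)))
        assert np.allclose(ssnr.values, lam2 / sig2, rtol=1e-10)


class TestVarianceCorrection:
    def test_one_third_maps_to_one_half(self):
        shells = build_shells((8,), 1.0)
        c = esfsc_closed_form(
            _profile(shells, np.array([0, 1, 1, 0, 0.0])), _profile(shells, np.ones(5))
        )
        manual = c.values.copy()
        corrected = variance_correction(c)
        ok = np.isfinite(manual) & ~np.isclose(manual, -1.0)  # pole excluded
        assert np.allclose(corrected.values[ok], 2 * manual[ok] / (1 + manual[ok]))
        # spot value
        assert 2 * (1 / 3) / (1 + 1 / 3) == pytest.approx(0.5)

    def test_fixed_points(self):
        shells = build_shells((8,), 1.0)
        vals = np.array([np.nan, 1.0, 0.0, 0.5, -1.0])
        from sfsc.correlation import CorrelationCurve

        c = CorrelationCurve(vals, shells, shells.frequencies, shells.counts, False, "sfsc_mean")
        out = variance_correction(c)
        assert out.values[1] == 1.0 and out.values[2] == 0.0
        assert np.isnan(out.values[4])  # pole flagged undefined
        assert np.isnan(out.values[0])  # undefined propagates

    def test_double_application_rejected(self):
        shells = build_shells((8,), 1.0)
        from sfsc.correlation import CorrelationCurve

        c = CorrelationCurve(np.zeros(5), shells, shells.frequencies, shells.counts, False, "sfsc_mean")
        with pytest.raises(ValueError, match="already"):
            variance_correction(variance_correction(c))

    def test_non_sfsc_curve_rejected(self, random_grid):
        g = random_grid((8, 8))
        with pytest.raises(ValueError, match="SFSC"):
            variance_correction(fsc(g, g))

    def test_corrected_esfsc_equals_efsc_under_assumptions(self):
        """2*ESFSC/(1+ESFSC) == EFSC exactly when the noise is flat and the
        partner shells carry no signal (random profiles, 1e-12)."""
        rng = np.random.default_rng(5)
        shells = build_shells((64,), 1.0)
        for _ in range(10):
            lam2 = np.zeros(33)
            lam2[:16] = rng.uniform(0.1, 10.0, size=16)
            sig2 = np.full(33, rng.uniform(0.1, 3.0))
            half = variance_correction(
                esfsc_closed_form(_profile(shells, lam2), _profile(shells, sig2))
            )
            full = efsc_closed_form(_profile(shells, lam2), _profile(shells, sig2))
            assert np.allclose(half.values[1:15], full.values[1:15], atol=1e-12)


class TestSfscUpsampled:
    def test_pure_whitened_noise_averages_to_zero(self):
        """The default gamma removes the noise term from the numerator."""
        acc = []
        for seed in range(50):
            g = RealGrid(np.random.default_rng(seed).normal(size=(32, 32)), 1.0)
            acc.append(sfsc_upsampled(g).values)
        acc = np.array(acc)
        mean = acc.mean(0)
        se = acc.std(0, ddof=1) / np.sqrt(len(acc))
        assert np.all(np.abs(mean[1:-1]) < 4 * se[1:-1] + 0.01)

    def test_gamma_zero_on_noise_gives_one(self):
        """Without noise subtraction the upsampled halves are identical below
        the original Nyquist, so the curve is ~1 (the ratio sigma^2/sigma^2)."""
        g = RealGrid(np.random.default_rng(0).normal(size=(32, 32)), 1.0)
        c = sfsc_upsampled(g, gamma=0.0)
        assert np.all(c.values[1:-1] > 0.999)

    def test_recovers_efsc_for_slowly_decaying_signal(self):
        """Flat-ish whitened signal: the plain corrected SFSC underestimates,
        the upsampled estimator matches the closed-form EFSC."""
        shape = (64, 64)
        shells = build_shells(shape, 0.5)
        lam2 = 8.0 * np.exp(-10.0 * shells.frequencies**2 / 2)  # slow decay, whitened units
        sig2 = np.ones_like(lam2)
        efsc = efsc_closed_form(_profile(shells, lam2), _profile(shells, sig2))
        accU, accP = [], []
        for seed in range(60):
            child = np.random.default_rng(3000 + seed)
            x = sample_field_from_profile(shells, lam2, child)
            e = sample_field_from_profile(shells, sig2, child)
            y = RealGrid(x.values + e.values, 0.5)
            accU.append(sfsc_upsampled(y).values)
            accP.append(variance_correction(sfsc(y)).values)
        mU = np.mean(accU, 0)
        with np.errstate(invalid="ignore"):
            mP = np.nanmean(np.array(accP)[:, 1:], 0)
        up_curve = sfsc_upsampled(RealGrid(np.zeros(shape), 0.5))
        sel = up_curve.counts[: len(mU)] >= 30  # sparse shells: O(1/n_r) ratio bias
        sel[0] = sel[-1] = False
        assert np.nanmax(np.abs(mU[sel] - efsc.values[: len(mU)][sel])) < 0.05
        # the plain corrected estimator underestimates somewhere
        diff = mP[: len(mP) - 1] - efsc.values[1 : len(mP)]
        assert np.nanmin(diff) < -0.05


class TestCurveContracts:
    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=20, deadline=None)
    def test_cauchy_schwarz_bound_on_random_inputs(self, seed):
        r = np.random.default_rng(seed)
        g = RealGrid(r.normal(size=(12, 12)), 1.0)
        for curve in (sfsc(g), fsc(g, RealGrid(r.normal(size=(12, 12)), 1.0))):
            assert np.all(np.abs(curve.values[curve.defined]) <= 1.0 + 1e-12)

    def test_csv_column_order_is_fixed(self, tmp_path, random_grid):
        import pandas as pd

        c = sfsc(random_grid((16, 16)))
        path = tmp_path / "curve.csv"
        from sfsc import write_curve_csv

        write_curve_csv(c, path)
        df = pd.read_csv(path)
        assert list(df.columns) == CURVE_COLUMNS

    def test_json_mirror_carries_provenance(self, tmp_path, random_grid):
        import json

        from sfsc import write_curve_json

        c = sfsc(random_grid((16, 16)))
        path = tmp_path / "curve.json"
        write_curve_json(c, path)
        payload = json.loads(path.read_text())
        assert payload["provenance"] == "sfsc_mean"
        assert payload["corrected"] is False
        assert len(payload["shells"]) == c.n_shells
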