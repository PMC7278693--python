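"""Scatter-correction and derivative operators against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milkcal import (
    DegenerateSpectrumError,
    InvariantError,
    apply_pretreatment,
    detrend,
    fit_pretreatment,
    gap_derivative,
    msc,
    parse_treatment,
    snv,
)
from milkcal.spectral_data import SpectralDataset


def brute_gap_derivative(x, d, g, s):
    """Independent brute-force of the stated convention: centred moving
    average (even windows shifted right), then d gap differences with
    h = ceil(g/2), keeping only fully-supported indices."""
    x = np.asarray(x, float)
    n = x.size
    hl, hr = (s - 1) // 2, s // 2
    sm = np.array([x[i - hl:i + hr + 1].mean() for i in range(hl, n - hr)])
    h = -(-g // 2)
    y = sm
    for _ in range(d):
        y = np.array([y[i + h] - y[i - h] for i in range(h, y.size - h)])
    return y


class TestSnv:
    def test_three_points(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2, 3])), [-1, 0, 1])

    def test_constant_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            snv(np.full(10, 3.2))

    def test_output_moments(self, rng):
        x = rng.normal(2, 5, 200)
        out = snv(x)
        assert abs(out.mean()) < 1e-12
        assert abs(out.std(ddof=1) - 1) < 1e-12

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, seed):
        x = np.random.default_rng(seed).normal(size=50)
        np.testing.assert_allclose(snv(snv(x)), snv(x), atol=1e-12)


class TestDetrend:
    def test_annihilates_quadratic(self):
        i = np.arange(60.0)
        y = 2 + 0.5 * i + 0.01 * i**2
        np.testing.assert_allclose(detrend(y), 0, atol=1e-9)

    def test_matches_polyfit_oracle(self, rng):
        i = np.arange(80.0)
        y = np.exp(-0.5 * ((i - 40) / 5) ** 2) + 0.002 * i**2 - 0.1 * i + 3
        expected = y - np.polyval(np.polyfit(i, y, 2), i)
        np.testing.assert_allclose(detrend(y), expected, atol=1e-10)

    def test_degree_zero_on_constant(self):
        np.testing.assert_allclose(detrend(np.full(5, 7.0), degree=0), 0, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(InvariantError):
            detrend(np.array([1.0, 2.0]), degree=2)


class TestMsc:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.m = np.abs(rng.normal(1, 0.3, 120)) + 0.5

    def test_identity(self):
        np.testing.assert_allclose(msc(self.m, self.m, "msc_standard"), self.m, atol=1e-12)

    def test_standard_inverts_affine(self):
        x = 2 * self.m + 3
        np.testing.assert_allclose(msc(x, self.m, "msc_standard"), self.m, atol=1e-10)

    def test_inverse_variant_algebra(self):
        # regressing m on x = 2m+3 gives a' = -3/2, b' = 1/2, so output is m
        x = 2 * self.m + 3
        np.testing.assert_allclose(msc(x, self.m, "msc_inverse"), self.m, atol=1e-9)

    def test_weighted_equals_standard_under_uniform_weights(self):
        x = 1.7 * self.m - 0.4
        w = np.full_like(self.m, 3.3)
        np.testing.assert_allclose(
            msc(x, self.m, "msc_weighted", weights=w),
            msc(x, self.m, "msc_standard"),
            atol=1e-10,
        )

    def test_degenerate_slope_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            msc(np.ones_like(self.m) * 2, self.m * 0 + 1.0, "msc_standard")


class TestGapDerivative:
    def test_constant_derivative_is_zero(self):
        out = gap_derivative(np.full(30, 4.2), 1, 4, 4)
        np.testing.assert_allclose(out, 0, atol=1e-12)

    def test_ramp_first_derivative(self):
        # h = ceil(4/2) = 2 so the gap difference of y(i)=i is 2h = 4
        out = gap_derivative(np.arange(30.0), 1, 4, 1)
        np.testing.assert_allclose(out, 4.0)

    def test_parabola_second_derivative(self):
        # h = 1: first pass 4i, second pass constant 8
        out = gap_derivative(np.arange(30.0) ** 2, 2, 2, 1)
        np.testing.assert_allclose(out, 8.0)

    @pytest.mark.parametrize("d,g,s", [(0, 0, 4), (0, 0, 5), (1, 4, 4),
                                       (1, 1, 4), (2, 8, 8), (2, 10, 10)])
    def test_matches_brute_force(self, rng, d, g, s):
        x = rng.normal(size=80).cumsum()
        np.testing.assert_allclose(
            gap_derivative(x, d, g, s), brute_gap_derivative(x, d, g, s), atol=1e-10
        )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15, deadline=None)
    def test_linearity(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=(2, 60))
        a, b = r.normal(size=2)
        lhs = gap_derivative(a * x + b * y, 1, 4, 4)
        rhs = a * gap_derivative(x, 1, 4, 4) + b * gap_derivative(y, 1, 4, 4)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_too_short_names_minimum(self):
        with pytest.raises(InvariantError, match="at least"):
            gap_derivative(np.arange(5.0), 2, 10, 10)


class TestApplyPretreatment:
    def _dataset(self, rng, n=8, p=60):
        axis = np.arange(400.0, 400 + 2 * p, 2.0)
        sig = np.abs(rng.normal(1, 0.3, (n, p))).cumsum(axis=1) / 10
        return SpectralDataset([f"s{i}" for i in range(n)], axis, sig, "nir")

    def test_none_is_identity(self, rng):
        ds = self._dataset(rng)
        fp = fit_pretreatment(ds, parse_treatment("None 0,0,1"))
        out = apply_pretreatment(ds, fp)
        np.testing.assert_array_equal(out.signal, ds.signal)
        np.testing.assert_array_equal(out.axis, ds.axis)

    def test_snv_detrend_composition(self, rng):
        ds = self._dataset(rng)
        fp = fit_pretreatment(ds, parse_treatment("SNV and Detrend 1,4,4"))
        out = apply_pretreatment(ds, fp)
        expected = np.stack([
            gap_derivative(detrend(snv(row)), 1, 4, 4) for row in ds.signal
        ])
        np.testing.assert_allclose(out.signal, expected, atol=1e-12)
        # derivative 1,4,4 trims (1+2, 2+2) points
        assert out.axis[0] == ds.axis[3] and out.axis[-1] == ds.axis[-5]

    def test_deterministic(self, rng):
        ds = self._dataset(rng)
        fp = fit_pretreatment(ds, parse_treatment("Standard MSC 1,4,4"))
        a = apply_pretreatment(ds, fp)
        b = apply_pretreatment(ds, fp)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_row_locality_of_non_msc(self, rng):
        """Applying a fitted non-MSC treatment to one sample must not depend
        on which other samples ride along."""
        ds = self._dataset(rng, n=6)
        fp = fit_pretreatment(ds, parse_treatment("SNV and Detrend 1,4,4"))
        full = apply_pretreatment(ds, fp)
        solo = apply_pretreatment(ds.subset(["s2"]), fp)
        np.testing.assert_array_equal(full.signal[2], solo.signal[0])

    def test_axis_mismatch_rejected(self, rng):
        ds = self._dataset(rng)
        fp = fit_pretreatment(ds, parse_treatment("SNV 0,0,1"))
        other = SpectralDataset(ds.sample_ids, ds.axis + 1.0, ds.signal, "nir")
        with pytest.raises(InvariantError):
            apply_pretreatment(other, fp)


def test_msc_recovers_scatter_free_spectra():
    """With identical chemistry, per-sample affine scatter is the only
    between-sample difference and standard MSC must undo it up to noise."""
    from dataclasses import replace
    from milkcal.simulate import (default_scenario, generate_concentrations,
                                  generate_spectra)

    cfg = default_scenario(n_samples=40, seed=9)
    cfg = replace(
        cfg,
        analytes=tuple(
            replace(a, sd=0.0) for a in cfg.analytes
        ),
        baseline_scale=0.0, noise_sd=0.005,
    )
    ref = generate_concentrations(cfg)
    clean = generate_spectra(ref, cfg, "nir", clean=True)
    noisy = generate_spectra(ref, cfg, "nir")
    fp = fit_pretreatment(noisy, parse_treatment("Standard MSC 0,0,1"))
    corrected = apply_pretreatment(noisy, fp)
    # scatter is gone: every corrected sample collapses onto the reference
    rmse_ref = np.sqrt(((corrected.signal - fp.reference_mean) ** 2).mean())
    assert rmse_ref <= 2 * cfg.noise_sd
    # and the reference itself is the true spectrum up to one global affine
    # map (the calibration set's mean scatter, which MSC cannot identify)
    b, a = np.polyfit(corrected.signal.mean(axis=0), clean.signal[0], 1)
    aligned = a + b * corrected.signal
    rmse_true = np.sqrt(((aligned - clean.signal) ** 2).mean())
    assert rmse_true <= 2 * cfg.noise_sd
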