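"""Synthetic-data generator: determinism, truncation, linearity, recovery."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from milkcal import InvariantError
from milkcal.simulate import (
    AnalyteSpec,
    Band,
    ScenarioConfig,
    default_scenario,
    generate_concentrations,
    generate_spectra,
    plant_outliers,
    simulate_dataset,
)


class TestDefaultScenario:
    def test_study_conditions(self):
        cfg = default_scenario()
        assert cfg.n_samples == 242
        vit_a = cfg.analyte("vitamin-A")
        assert (vit_a.mean, vit_a.sd) == (0.52, 0.24)
        atbc = cfg.analyte("all-trans-beta-carotene")
        assert (atbc.mean, atbc.sd) == (0.23, 0.11)
        assert len(cfg.analytes) == 10

    def test_correlation_matrix_is_psd(self):
        cfg = default_scenario()
        assert np.linalg.eigvalsh(cfg.correlation).min() >= -1e-10
        i = [a.name for a in cfg.analytes]
        r = cfg.correlation[i.index("zeaxanthin"), i.index("cis9-beta-carotene")]
        assert r == pytest.approx(0.95, abs=1e-9)

    def test_axes_are_desk_scale(self):
        cfg = default_scenario()
        total = sum(len(ax) for ax in cfg.axes.values())
        assert total < 1200
        assert np.all(np.diff(cfg.axes["nir"]) == 8.0)


class TestConcentrations:
    def test_deterministic(self):
        cfg = default_scenario(n_samples=30, seed=5)
        a = generate_concentrations(cfg)
        b = generate_concentrations(cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nonnegative(self):
        cfg = default_scenario(n_samples=500, seed=6)
        assert generate_concentrations(cfg).values.min() >= 0

    def test_zero_sd_gives_mean_vector(self):
        cfg = default_scenario(n_samples=12, seed=1)
        cfg = replace(cfg, analytes=tuple(replace(a, sd=0.0) for a in cfg.analytes))
        ref = generate_concentrations(cfg)
        means = np.array([a.mean for a in cfg.analytes])
        np.testing.assert_allclose(ref.values, np.tile(means, (12, 1)))

    def test_mean_recovery_vs_truncated_normal_oracle(self):
        """Single analyte at the emulated study's all-trans-beta-carotene
        parameters: the sample mean must match the analytic mean of the
        zero-truncated normal (resampling realizes exactly that law)."""
        a = AnalyteSpec("all-trans-beta-carotene", "ug/mL", 0.23, 0.11)
        cfg = ScenarioConfig((a,), np.eye(1), n_samples=100_000, axes={}, seed=3)
        ref = generate_concentrations(cfg)
        alpha = -0.23 / 0.11
        expected = 0.23 + 0.11 * stats.norm.pdf(alpha) / stats.norm.sf(alpha)
        assert ref.values.mean() == pytest.approx(expected, rel=0.005)
        # and the truncation bias itself is small (a couple of percent)
        assert abs(ref.values.mean() - 0.23) / 0.23 < 0.03

    def test_non_psd_matrix_rejected(self):
        a = AnalyteSpec("x", "ug/mL", 1, 0.1)
        b = AnalyteSpec("y", "ug/mL", 1, 0.1)
        c = AnalyteSpec("z", "ug/mL", 1, 0.1)
        R = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]])
        cfg = ScenarioConfig((a, b, c), R, n_samples=5, axes={}, seed=0)
        with pytest.raises(InvariantError, match="semi-definite"):
            generate_concentrations(cfg)


class TestSpectra:
    def test_linear_in_concentration_when_clean(self):
        cfg = default_scenario(n_samples=25, seed=8)
        ref = generate_concentrations(cfg)
        ds = generate_spectra(ref, cfg, "nir", clean=True)
        # clean spectra are affine in concentrations: centred signal lies in
        # the span of the centred concentration matrix (linear solve)
        C = ref.values - ref.values.mean(axis=0)
        S = ds.signal - ds.signal.mean(axis=0)
        B, *_ = np.linalg.lstsq(C, S, rcond=None)
        np.testing.assert_allclose(C @ B, S, atol=1e-8)

    def test_single_band_proportionality(self):
        a = AnalyteSpec("x", "ug/mL", 1.0, 0.5,
                        bands={"nir": (Band(500.0, 30.0, 2.0),)})
        axis = np.arange(400.0, 700.0, 4.0)
        cfg = ScenarioConfig((a,), np.eye(1), n_samples=15,
                             axes={"nir": axis}, baseline_scale=0.0,
                             scatter=(0.0, 0.0), noise_sd=0.0, seed=2)
        ref = generate_concentrations(cfg)
        ds = generate_spectra(ref, cfg, "nir")
        j = np.argmin(np.abs(axis - 500.0))
        np.testing.assert_allclose(ds.signal[:, j], 2.0 * ref.values[:, 0],
                                   rtol=1e-12)

    def test_deterministic_per_modality(self):
        cfg = default_scenario(n_samples=10, seed=4)
        ref = generate_concentrations(cfg)
        a = generate_spectra(ref, cfg, "mir_atr")
        b = generate_spectra(ref, cfg, "mir_atr")
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_missing_bands_error_lists_analytes(self):
        a = AnalyteSpec("x", "ug/mL", 1.0, 0.1, bands={})
        cfg = ScenarioConfig((a,), np.eye(1), n_samples=5,
                             axes={"nir": np.arange(400.0, 500.0, 4.0)}, seed=0)
        ref = generate_concentrations(cfg)
        with pytest.raises(InvariantError, match="x"):
            generate_spectra(ref, cfg, "nir")

    def test_simulate_dataset_bundles_all_modalities(self):
        cfg = default_scenario(n_samples=8, seed=3)
        ref, spectra = simulate_dataset(cfg)
        assert set(spectra) == {"nir", "mir_atr", "sync_fluor"}
        for ds in spectra.values():
            assert ds.sample_ids == ref.sample_ids


class TestPlantOutliers:
    def test_identity_when_none_planted(self, small_dataset):
        _, ref, ds = small_dataset
        ds2, ref2, planted = plant_outliers(ds, ref, 0, 0, 5.0, seed=1)
        np.testing.assert_array_equal(ds2.signal, ds.signal)
        np.testing.assert_array_equal(ref2.values, ref.values)
        assert planted == {"T": [], "H": []}

    def test_planted_ids_are_sample_ids(self, small_dataset):
        _, ref, ds = small_dataset
        _, _, planted = plant_outliers(ds, ref, 2, 3, 5.0, seed=2)
        all_ids = set(ds.sample_ids)
        assert set(planted["T"]) <= all_ids and set(planted["H"]) <= all_ids
        assert not set(planted["T"]) & set(planted["H"])

    def test_magnitude_must_be_positive(self, small_dataset):
        _, ref, ds = small_dataset
        with pytest.raises(InvariantError):
            plant_outliers(ds, ref, 1, 0, 0.0, seed=1)


def test_correlation_structure_converges():
    """Sample correlations approach the configured matrix when truncation is
    negligible (means shifted far from zero, same correlation pattern)."""
    cfg = default_scenario(n_samples=10_000, seed=19)
    shifted = tuple(replace(a, mean=a.mean + 10 * a.sd) for a in cfg.analytes)
    cfg = replace(cfg, analytes=shifted)
    ref = generate_concentrations(cfg)
    sample_corr = np.corrcoef(ref.values.T)
    assert np.abs(sample_corr - cfg.correlation).max() <= 0.05
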