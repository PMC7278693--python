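"""Synthetic milk dataset generator.

Forward model per modality: each analyte contributes Gaussian absorption /
emission bands scaled by its concentration; on top of that Beer-Lambert-like
mixture each sample gets a random polynomial baseline, a per-sample affine
scatter distortion (slope near 1, small offset) and iid additive noise:

    x_i = slope_i * (C_i @ B + baseline_i) + offset_i + noise_i

Concentrations are drawn from a truncated multivariate normal whose means,
standard deviations and correlation structure default to the composition
statistics of the 242-sample cow-milk study the package emulates.  The bands
themselves are synthetic: they make each analyte identifiable without
claiming spectral realism for milk.

All randomness flows through a single seed; per-modality sub-streams are
derived with ``numpy.random.SeedSequence`` so datasets are reproducible
independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvariantError
from .spectral_data import ReferenceTable, SpectralDataset

__all__ = [
    "Band",
    "AnalyteSpec",
    "ScenarioConfig",
    "generate_concentrations",
    "generate_spectra",
    "plant_outliers",
    "default_scenario",
    "simulate_dataset",
    "dynamic_range",
]

_EIG_TOL = 1e-6  # correlation eigenvalues below -_EIG_TOL are an error


@dataclass(frozen=True)
class Band:
    center: float
    width: float      # Gaussian sigma, in axis units
    intensity: float  # signal per unit concentration at the band centre

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvariantError("band width must be positive")


@dataclass(frozen=True)
class AnalyteSpec:
    name: str
    unit: str
    mean: float
    sd: float
    bands: dict[str, tuple[Band, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvariantError("sd must be nonnegative")


@dataclass(frozen=True)
class ScenarioConfig:
    analytes: tuple[AnalyteSpec, ...]
    correlation: np.ndarray           # (k, k) symmetric, unit diagonal
    n_samples: int
    axes: dict[str, np.ndarray]       # modality -> axis grid
    #: constant background spectrum per modality (broad matrix bands shared
    #: by every sample, e.g. water/fat absorption); band intensities here are
    #: absolute signal, not per unit concentration
    background: dict[str, tuple[Band, ...]] = field(default_factory=dict)
    baseline_degree: int = 2
    baseline_scale: float = 0.1
    scatter: tuple[float, float] = (0.05, 0.02)   # (slope sd, offset sd)
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.correlation, dtype=float)
        k = len(self.analytes)
        if R.shape != (k, k):
            raise InvariantError(f"correlation must be {k}x{k}")
        if not np.allclose(R, R.T, atol=1e-12):
            raise InvariantError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise InvariantError("correlation diagonal must be 1")
        object.__setattr__(self, "correlation", R)
        object.__setattr__(self, "analytes", tuple(self.analytes))

    def analyte(self, name: str) -> AnalyteSpec:
        for a in self.analytes:
            if a.name == name:
                return a
        raise InvariantError(f"no analyte named {name!r} in scenario")


def _chol_clipped(R: np.ndarray) -> np.ndarray:
    eig, V = np.linalg.eigh(R)
    if eig.min() < -_EIG_TOL:
        raise InvariantError(
            f"correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eig.min():.3g})"
        )
    eig = np.clip(eig, 0.0, None)
    return V * np.sqrt(eig)  # L with L @ L.T = clipped R


def generate_concentrations(cfg: ScenarioConfig, seed: int | None = None) -> ReferenceTable:
    """Draw correlated concentrations, truncated at zero by per-sample
    resampling (at most 100 redraws, then clamping to zero)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    k = len(cfg.analytes)
    mu = np.array([a.mean for a in cfg.analytes])
    sig = np.array([a.sd for a in cfg.analytes])
    L = _chol_clipped(cfg.correlation)
    n = cfg.n_samples
    vals = mu + (rng.standard_normal((n, k)) @ L.T) * sig
    for _ in range(100):
        bad = np.flatnonzero((vals < 0).any(axis=1))
        if bad.size == 0:
            break
        vals[bad] = mu + (rng.standard_normal((bad.size, k)) @ L.T) * sig
    vals = np.clip(vals, 0.0, None)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return ReferenceTable(ids, [a.name for a in cfg.analytes],
                          [a.unit for a in cfg.analytes], vals)


def _band_matrix(cfg: ScenarioConfig, modality: str) -> np.ndarray:
    try:
        axis = np.asarray(cfg.axes[modality], dtype=float)
    except KeyError:
        raise InvariantError(f"scenario defines no axis for modality {modality!r}") from None
    missing = [a.name for a in cfg.analytes if not a.bands.get(modality)]
    if missing:
        raise InvariantError(f"analytes without {modality} bands: {missing}")
    B = np.zeros((len(cfg.analytes), axis.size))
    for j, a in enumerate(cfg.analytes):
        for band in a.bands[modality]:
            B[j] += band.intensity * np.exp(-0.5 * ((axis - band.center) / band.width) ** 2)
    return B


def _modality_rng(cfg: ScenarioConfig, modality: str, seed: int | None) -> np.random.Generator:
    base = cfg.seed if seed is None else seed
    key = sorted(cfg.axes).index(modality) if modality in cfg.axes else 97
    return np.random.default_rng(np.random.SeedSequence([int(base), key]))


def generate_spectra(
    ref: ReferenceTable,
    cfg: ScenarioConfig,
    modality: str,
    seed: int | None = None,
    clean: bool = False,
) -> SpectralDataset:
    """Forward-model spectra for the concentrations in ``ref``.

    ``clean`` disables baseline, scatter and noise, leaving the pure
    concentration-linear mixture (useful for oracles and dynamic-range
    measurements).
    """
    names = [a.name for a in cfg.analytes]
    C = np.column_stack([ref.column(nm) for nm in names])
    B = _band_matrix(cfg, modality)
    axis = np.asarray(cfg.axes[modality], dtype=float)
    signal = C @ B
    for band in cfg.background.get(modality, ()):
        signal = signal + band.intensity * np.exp(
            -0.5 * ((axis - band.center) / band.width) ** 2
        )
    if not clean:
        rng = _modality_rng(cfg, modality, seed)
        n, p = signal.shape
        u = np.linspace(0.0, 1.0, p)
        coefs = rng.normal(0.0, cfg.baseline_scale, size=(n, cfg.baseline_degree + 1))
        baseline = sum(coefs[:, [d]] * u**d for d in range(cfg.baseline_degree + 1))
        slope = rng.normal(1.0, cfg.scatter[0], size=(n, 1))
        offset = rng.normal(0.0, cfg.scatter[1], size=(n, 1))
        signal = slope * (signal + baseline) + offset
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)
    return SpectralDataset(ref.sample_ids, axis, signal, modality)


def dynamic_range(ref: ReferenceTable, cfg: ScenarioConfig, modality: str) -> float:
    """Peak-to-peak range of the clean (noise/baseline/scatter-free) signal."""
    clean = generate_spectra(ref, cfg, modality, clean=True)
    return float(clean.signal.max() - clean.signal.min())


def plant_outliers(
    ds: SpectralDataset,
    ref: ReferenceTable,
    n_T: int,
    n_H: int,
    magnitude: float,
    seed: int,
    analyte: str | None = None,
):
    """Plant gross errors to exercise the outlier rules.

    ``n_T`` samples get their reference value for ``analyte`` (default: the
    first analyte) shifted by ``magnitude * sd(y)``; ``n_H`` other samples
    get their spectra multiplied by ``magnitude``.  Returns
    ``(ds', ref', {"T": ids, "H": ids})``.
    """
    if magnitude <= 0:
        raise InvariantError("magnitude must be positive")
    if n_T < 0 or n_H < 0 or n_T + n_H > ds.n_samples:
        raise InvariantError("need 0 <= n_T + n_H <= n_samples")
    if tuple(ds.sample_ids) != tuple(ref.sample_ids):
        raise InvariantError("dataset and reference table must share sample ids")
    rng = np.random.default_rng(seed)
    picks = rng.choice(ds.n_samples, size=n_T + n_H, replace=False)
    t_rows, h_rows = picks[:n_T], picks[n_T:]
    name = analyte or ref.analytes[0]
    j = ref.analytes.index(name)
    values = ref.values.copy()
    values[t_rows, j] += magnitude * values[:, j].std(ddof=1)
    signal = ds.signal.copy()
    signal[h_rows] *= magnitude
    ds2 = ds.with_signal(signal)
    ref2 = ReferenceTable(ref.sample_ids, ref.analytes, ref.units, values, dict(ref.sel))
    planted = {"T": [ds.sample_ids[i] for i in t_rows],
               "H": [ds.sample_ids[i] for i in h_rows]}
    return ds2, ref2, planted


# ---------------------------------------------------------------------------
# default scenario
# ---------------------------------------------------------------------------

#: (name, unit, mean, sd) — composition statistics of the emulated study's
#: calibration set (concentrations in the stated units).
_DEFAULT_ANALYTES = (
    ("cis9-beta-carotene", "ug/mL", 0.02, 0.01),
    ("all-trans-beta-carotene", "ug/mL", 0.23, 0.11),
    ("beta-cryptoxanthin", "ug/mL", 0.03, 0.02),
    ("lutein", "ug/mL", 0.17, 0.07),
    ("zeaxanthin", "ug/mL", 0.10, 0.07),
    ("vitamin-A", "ug retinol/mL", 0.52, 0.24),
    ("alpha-tocopherol", "ug/mL", 1.18, 0.49),
    ("C14:0", "g/100g", 11.55, 2.26),
    ("C16:0", "g/100g", 28.07, 5.96),
    ("cis9-C18:1", "g/100g", 19.36, 4.24),
)

#: correlations embedded in the default scenario.  The 0.95 pair mirrors the
#: strongest carotenoid correlation in the emulated dataset; the rest sit in
#: the ranges that dataset reports (carotenoids strongly mutual, fatty acids
#: mutually correlated, micronutrients nearly uncorrelated with fat).
_DEFAULT_CORR_PAIRS = {
    (0, 1): 0.70, (0, 2): 0.86, (0, 3): 0.84, (0, 4): 0.95,
    (1, 2): 0.65, (1, 3): 0.65, (1, 4): 0.70,
    (2, 3): 0.84, (2, 4): 0.85,
    (3, 4): 0.86,
    (5, 0): 0.30, (5, 1): 0.30, (5, 2): 0.30, (5, 3): 0.30, (5, 4): 0.30,
    (6, 0): 0.20, (6, 1): 0.20, (6, 2): 0.20, (6, 3): 0.20, (6, 4): 0.20,
    (6, 5): 0.20,
    (7, 8): 0.80, (7, 9): -0.55, (8, 9): -0.60,
}

_NIR_CENTERS = (460, 560, 660, 760, 900, 1050, 1200, 1450, 1750, 2100)
_MIR_CENTERS = (800, 1050, 1250, 1450, 1650, 1850, 2300, 2850, 2950, 3300)
_FLUOR_CENTERS = (350, 375, 400, 425, 450, 475, 500, 530, 560, 600)


def default_scenario(n_samples: int = 242, seed: int = 0) -> ScenarioConfig:
    """The stand-in for the emulated milk study: 10 analytes with its
    composition means/SDs and correlation structure, 242 samples, three
    modality grids decimated to desk scale (NIR every 8 nm, MIR-ATR every
    16 cm^-1, synchronous fluorescence every 2 nm)."""
    k = len(_DEFAULT_ANALYTES)
    R = np.eye(k)
    for (i, j), r in _DEFAULT_CORR_PAIRS.items():
        R[i, j] = R[j, i] = r
    # nudge onto the PSD cone if the hand-set pattern is slightly indefinite
    eig, V = np.linalg.eigh(R)
    if eig.min() < 0:
        R = (V * np.clip(eig, 1e-6, None)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
    analytes = []
    for idx, (name, unit, mean, sd) in enumerate(_DEFAULT_ANALYTES):
        scale = 1.0 / mean  # comparable signal contribution per analyte
        bands = {
            "nir": (Band(_NIR_CENTERS[idx], 60.0, scale),),
            "mir_atr": (Band(_MIR_CENTERS[idx], 80.0, scale),),
            "sync_fluor": (Band(_FLUOR_CENTERS[idx], 15.0, scale),),
        }
        analytes.append(AnalyteSpec(name, unit, mean, sd, bands))
    axes = {
        "nir": np.arange(400.0, 2500.0 + 1, 8.0),
        "mir_atr": np.arange(700.0, 4000.0 + 1, 16.0),
        "sync_fluor": np.arange(330.0, 630.0 + 1, 2.0),
    }
    # broad matrix background (water/fat-like) dominating each spectrum, so
    # per-sample scatter is a near-affine distortion as in real milk spectra
    background = {
        "nir": (Band(1450.0, 300.0, 3.0), Band(1940.0, 250.0, 4.0)),
        "mir_atr": (Band(1640.0, 200.0, 3.0), Band(3350.0, 350.0, 4.0)),
        "sync_fluor": (Band(400.0, 80.0, 3.0), Band(520.0, 100.0, 2.0)),
    }
    return ScenarioConfig(
        analytes=tuple(analytes), correlation=R, n_samples=n_samples,
        axes=axes, background=background, baseline_degree=2, baseline_scale=0.1,
        scatter=(0.15, 0.05), noise_sd=0.01, seed=seed,
    )


def simulate_dataset(cfg: ScenarioConfig, seed: int | None = None):
    """Concentrations plus spectra for every modality in the scenario."""
    ref = generate_concentrations(cfg, seed)
    spectra = {m: generate_spectra(ref, cfg, m, seed) for m in sorted(cfg.axes)}
    return ref, spectra
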