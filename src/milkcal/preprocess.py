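"""Scatter corrections and gap-segment derivatives.

All operators act row-locally on single spectra except the MSC family, which
needs the calibration set's mean spectrum (and, for the weighted variant, the
between-sample variance per wavelength).  :func:`fit_pretreatment` captures
those calibration statistics in a :class:`FittedPretreatment` so the same
transform can be replayed on new samples without touching their neighbours.

Order of operations when applying a full treatment: axis window -> scatter
correction -> gap-segment derivative.  The derivative truncates edges where
its stencil would fall outside the grid; the shortened axis is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSpectrumError, InvariantError
from .spectral_data import PreprocessSpec, SpectralDataset, restrict_axis

__all__ = [
    "snv",
    "detrend",
    "msc",
    "gap_derivative",
    "FittedPretreatment",
    "fit_pretreatment",
    "apply_pretreatment",
]

_VAR_FLOOR = 1e-12     # weighted-MSC variance floor
_SLOPE_FLOOR = 1e-12   # MSC degenerate-slope threshold


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum to (0, 1).

    Uses the sample standard deviation (n-1 denominator).
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise InvariantError("SNV needs at least 2 points")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSpectrumError("SNV undefined for a constant spectrum")
    return (x - x.mean()) / sd


def detrend(spectrum: np.ndarray, degree: int = 2) -> np.ndarray:
    """Remove a least-squares polynomial (in the axis *index*) of ``degree``."""
    x = np.asarray(spectrum, dtype=float)
    if x.size <= degree:
        raise InvariantError(f"detrend degree {degree} needs > {degree} points, got {x.size}")
    idx = np.arange(x.size, dtype=float)
    coef = np.polynomial.polynomial.polyfit(idx, x, degree)
    return x - np.polynomial.polynomial.polyval(idx, coef)


def msc(
    spectrum: np.ndarray,
    reference_mean: np.ndarray,
    variant: str = "msc_standard",
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Multiplicative scatter correction against a reference mean spectrum.

    standard:  regress x = a + b*m, return (x - a) / b.
    inverse:   regress m = a' + b'*x, return a' + b'*x.
    weighted:  as standard but weighted least squares; ``weights`` are
               1/var_j with var_j the between-sample variance per wavelength
               in the calibration set (floored at 1e-12).
    """
    x = np.asarray(spectrum, dtype=float)
    m = np.asarray(reference_mean, dtype=float)
    if x.shape != m.shape:
        raise InvariantError("spectrum and reference mean must share the axis")
    if variant == "msc_inverse":
        a, b = _wls_line(x, m, None)
        return a + b * x
    if variant == "msc_weighted":
        if weights is None:
            raise InvariantError("weighted MSC requires per-wavelength weights")
        a, b = _wls_line(m, x, np.asarray(weights, dtype=float))
    elif variant == "msc_standard":
        a, b = _wls_line(m, x, None)
    else:
        raise InvariantError(f"unknown MSC variant {variant!r}")
    if abs(b) < _SLOPE_FLOOR:
        raise DegenerateSpectrumError(f"MSC slope {b:.3g} below {_SLOPE_FLOOR}")
    return (x - a) / b


def _wls_line(u: np.ndarray, v: np.ndarray, w: np.ndarray | None) -> tuple[float, float]:
    """(Weighted) least-squares fit v = a + b*u; returns (a, b)."""
    if w is None:
        w = np.ones_like(u)
    sw = w.sum()
    ubar = (w * u).sum() / sw
    vbar = (w * v).sum() / sw
    duv = (w * (u - ubar) * (v - vbar)).sum()
    duu = (w * (u - ubar) ** 2).sum()
    if duu < _SLOPE_FLOOR:
        raise DegenerateSpectrumError("reference spectrum has (weighted) zero variance")
    b = duv / duu
    return vbar - b * ubar, b


def _smooth_window(s: int) -> tuple[int, int]:
    """Left/right half-widths of the moving-average window of size s.

    Odd s is centred; even s sits with its midpoint right of the centre
    point (e.g. s = 4 averages offsets -1..+2).
    """
    return (s - 1) // 2, s // 2


def derivative_margin(d: int, g: int, s: int) -> tuple[int, int]:
    """Points lost at the (left, right) edges by the d,g,s operator."""
    hl, hr = _smooth_window(s)
    h = math.ceil(g / 2) if d >= 1 else 0
    return hl + d * h, hr + d * h


def gap_derivative(spectrum: np.ndarray, d: int, g: int, s: int) -> np.ndarray:
    """Gap-segment derivative coded ``d,g,s``.

    The spectrum is first smoothed with a centred moving average of ``s``
    points, then differenced ``d`` times with the gap operator
    ``y(i+h) - y(i-h)`` where ``h = ceil(g/2)``.  Only indices whose full
    stencil exists are returned, so the output is shorter by
    :func:`derivative_margin`.
    """
    if d not in (0, 1, 2):
        raise InvariantError(f"derivative order must be 0, 1 or 2, got {d}")
    spec = PreprocessSpec(scatter="none", d=d, g=g, s=s)  # validates the triple
    x = np.asarray(spectrum, dtype=float)
    ml, mr = derivative_margin(d, g, s)
    if x.size - ml - mr < 1:
        raise InvariantError(
            f"treatment {spec.d},{spec.g},{spec.s} needs at least {ml + mr + 1} "
            f"points, got {x.size}"
        )
    y = np.convolve(x, np.full(s, 1.0 / s), mode="valid") if s > 1 else x
    h = math.ceil(g / 2)
    for _ in range(d):
        y = y[2 * h:] - y[:-2 * h]
    return y


@dataclass(frozen=True)
class FittedPretreatment:
    """A PreprocessSpec bound to the calibration statistics it needs.

    ``reference_mean`` (and ``msc_weights`` for the weighted variant) are the
    calibration-set mean spectrum / inverse between-sample variances on the
    windowed axis; both are None unless the scatter method is an MSC variant.
    ``output_axis`` is the axis after windowing and derivative truncation.
    """

    spec: PreprocessSpec
    input_axis: np.ndarray
    output_axis: np.ndarray
    reference_mean: np.ndarray | None = None
    msc_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        needs_ref = self.spec.scatter in ("msc_standard", "msc_weighted", "msc_inverse")
        if needs_ref != (self.reference_mean is not None):
            raise InvariantError("reference_mean present iff scatter is an MSC variant")
        if self.spec.scatter == "msc_weighted" and self.msc_weights is None:
            raise InvariantError("weighted MSC needs fitted weights")


def fit_pretreatment(calibration: SpectralDataset, spec: PreprocessSpec) -> FittedPretreatment:
    """Capture the calibration statistics a treatment needs, then validate
    that it can run on this axis at all."""
    ds = calibration
    if spec.axis_window is not None:
        ds = restrict_axis(ds, *spec.axis_window)
    ref_mean = weights = None
    if spec.scatter in ("msc_standard", "msc_weighted", "msc_inverse"):
        ref_mean = ds.signal.mean(axis=0)
        if spec.scatter == "msc_weighted":
            var = ds.signal.var(axis=0, ddof=1) if ds.n_samples > 1 else np.zeros(ds.n_points)
            weights = 1.0 / np.maximum(var, _VAR_FLOOR)
    ml, mr = derivative_margin(spec.d, spec.g, spec.s)
    if ds.n_points - ml - mr < 1:
        raise InvariantError(
            f"treatment {spec.code!r} needs at least {ml + mr + 1} points, "
            f"axis has {ds.n_points}"
        )
    out_axis = ds.axis[ml: ds.n_points - mr]
    return FittedPretreatment(spec, ds.axis, out_axis, ref_mean, weights)


def apply_pretreatment(ds: SpectralDataset, fp: FittedPretreatment) -> SpectralDataset:
    """Apply a fitted treatment: window -> scatter -> derivative."""
    spec = fp.spec
    if spec.axis_window is not None:
        ds = restrict_axis(ds, *spec.axis_window)
    if ds.axis.shape != fp.input_axis.shape or not np.allclose(
        ds.axis, fp.input_axis, rtol=1e-9, atol=0.0
    ):
        raise InvariantError("dataset axis differs from the axis the treatment was fitted on")
    rows = ds.signal
    out = np.empty_like(rows)
    for i, x in enumerate(rows):
        if spec.scatter == "snv":
            x = snv(x)
        elif spec.scatter == "detrend":
            x = detrend(x)
        elif spec.scatter == "snv_detrend":
            x = detrend(snv(x))
        elif spec.scatter in ("msc_standard", "msc_inverse", "msc_weighted"):
            x = msc(x, fp.reference_mean, spec.scatter, fp.msc_weights)
        out[i] = x
    if spec.d >= 1 or spec.s > 1:
        out = np.stack([gap_derivative(row, spec.d, spec.g, spec.s) for row in out])
    return SpectralDataset(ds.sample_ids, fp.output_axis, out, ds.modality)
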