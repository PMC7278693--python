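"""Data model and I/O for spectra, reference chemistry and pretreatment codes.

Spectra are stored *wide*: one row per sample, one column per axis point, the
axis itself carried in the CSV header so the grid is single-sourced.  The
reference-chemistry table uses ``name:unit`` column headers and may carry an
optional ``SEL`` row holding the standard error of laboratory per analyte.

Pretreatment codes follow the WinISI-style convention used throughout milk
NIRS work: a scatter-correction name followed by a ``d,g,s`` triple, e.g.
``"SNV and Detrend 1,4,4"`` (first derivative, gap 4 points, smooth 4 points).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InvariantError

__all__ = [
    "SpectralDataset",
    "ReferenceTable",
    "PreprocessSpec",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
    "parse_treatment",
    "format_treatment",
    "restrict_axis",
]

#: modality tag -> axis unit.  Front-face fluorescence tags look like
#: ``ff_fluor:carotene``; all fluorescence axes are in nm.
_MODALITY_UNITS = {"nir": "nm", "mir_atr": "cm-1", "sync_fluor": "nm"}

#: accepted concentration units, normalised (µ -> u, spaces collapsed)
_KNOWN_UNITS = {
    "ug/mL",
    "ug retinol/mL",
    "g/100g",
    "g/100g FA",
    "g/kg",
    "pg/mL",
    "ng/mL",
    "a.u.",
}


def axis_unit_for(modality: str) -> str:
    if modality.startswith("ff_fluor:"):
        return "nm"
    try:
        return _MODALITY_UNITS[modality]
    except KeyError:
        raise InvariantError(f"unknown modality {modality!r}") from None


def _normalise_unit(unit: str) -> str:
    u = unit.replace("µ", "u").replace("μ", "u").strip()
    u = re.sub(r"\s+", " ", u)
    u = u.replace("g/100 g", "g/100g")
    if u not in _KNOWN_UNITS:
        raise FormatError(f"unknown unit {unit!r} (known: {sorted(_KNOWN_UNITS)})")
    return u


@dataclass(frozen=True)
class SpectralDataset:
    """Samples x axis-grid signal matrix for one spectroscopy modality."""

    sample_ids: tuple[str, ...]
    axis: np.ndarray          # strictly monotone, shape (p,)
    signal: np.ndarray        # shape (n, p)
    modality: str

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        if signal.ndim != 2:
            raise InvariantError("signal must be a 2-D matrix")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if len(self.sample_ids) != signal.shape[0]:
            raise InvariantError(
                f"{len(self.sample_ids)} sample ids but {signal.shape[0]} signal rows"
            )
        if axis.ndim != 1 or axis.size != signal.shape[1]:
            raise InvariantError(
                f"axis has {axis.size} points but signal has {signal.shape[1]} columns"
            )
        d = np.diff(axis)
        if axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise InvariantError("axis must be strictly monotone")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise InvariantError(f"duplicate sample ids: {dupes}")
        if not np.all(np.isfinite(signal)):
            raise InvariantError("signal contains missing/non-finite values")
        self.axis.setflags(write=False)
        self.signal.setflags(write=False)
        axis_unit_for(self.modality)  # validates the tag

    @property
    def axis_unit(self) -> str:
        return axis_unit_for(self.modality)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_points(self) -> int:
        return self.signal.shape[1]

    def with_signal(self, signal: np.ndarray, axis: np.ndarray | None = None) -> "SpectralDataset":
        return SpectralDataset(
            self.sample_ids, self.axis if axis is None else axis, signal, self.modality
        )

    def subset(self, ids) -> "SpectralDataset":
        """Row-subset by sample id, preserving the requested order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[str(s)] for s in ids]
        except KeyError as exc:
            raise InvariantError(f"sample id {exc.args[0]!r} not in dataset") from None
        return SpectralDataset(
            [self.sample_ids[i] for i in rows], self.axis, self.signal[rows], self.modality
        )


@dataclass(frozen=True)
class ReferenceTable:
    """Reference-chemistry concentrations per sample, one column per analyte.

    ``sel`` optionally stores the standard error of laboratory for each
    analyte (same unit as the analyte); it is metadata only and never enters
    any computation here.
    """

    sample_ids: tuple[str, ...]
    analytes: tuple[str, ...]
    units: tuple[str, ...]
    values: np.ndarray        # (n, k), nonnegative
    sel: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "analytes", tuple(self.analytes))
        object.__setattr__(self, "units", tuple(_normalise_unit(u) for u in self.units))
        if values.shape != (len(self.sample_ids), len(self.analytes)):
            raise InvariantError("values shape does not match ids x analytes")
        if len(self.units) != len(self.analytes):
            raise InvariantError("one unit per analyte required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvariantError("duplicate sample ids in reference table")
        if not np.all(np.isfinite(values)):
            raise InvariantError("reference values contain missing entries")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise InvariantError(
                f"negative concentration {values[i, j]} for sample "
                f"{self.sample_ids[i]!r}, analyte {self.analytes[j]!r}"
            )
        self.values.setflags(write=False)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, analyte: str) -> np.ndarray:
        try:
            j = self.analytes.index(analyte)
        except ValueError:
            raise InvariantError(f"analyte {analyte!r} not in reference table") from None
        return self.values[:, j]

    def unit(self, analyte: str) -> str:
        return self.units[self.analytes.index(analyte)]

    def subset(self, ids) -> "ReferenceTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[str(s)] for s in ids]
        except KeyError as exc:
            raise InvariantError(f"sample id {exc.args[0]!r} not in table") from None
        return ReferenceTable(
            [self.sample_ids[i] for i in rows], self.analytes, self.units,
            self.values[rows], dict(self.sel),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.analytes))


# ---------------------------------------------------------------------------
# pretreatment codes
# ---------------------------------------------------------------------------

#: printed scatter vocabulary -> internal name.  "MSC" with no qualifier is
#: standard MSC (the printed tables use the two interchangeably).
_SCATTER_ALIASES = {
    "none": "none",
    "snv": "snv",
    "detrend": "detrend",
    "snv and detrend": "snv_detrend",
    "msc": "msc_standard",
    "standard msc": "msc_standard",
    "weighted msc": "msc_weighted",
    "inverse msc": "msc_inverse",
}

_SCATTER_CANONICAL = {
    "none": "None",
    "snv": "SNV",
    "detrend": "Detrend",
    "snv_detrend": "SNV and Detrend",
    "msc_standard": "Standard MSC",
    "msc_weighted": "Weighted MSC",
    "msc_inverse": "Inverse MSC",
}

SCATTER_METHODS = tuple(_SCATTER_CANONICAL)


@dataclass(frozen=True)
class PreprocessSpec:
    """Scatter correction plus a ``d,g,s`` derivative triple.

    d: derivative order; g: gap in points; s: smoothing segment in points.
    ``axis_window`` optionally restricts the axis to ``(lo, hi)`` before any
    other operation.
    """

    scatter: str = "none"
    d: int = 0
    g: int = 0
    s: int = 1
    axis_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.scatter not in _SCATTER_CANONICAL:
            raise InvariantError(f"unknown scatter method {self.scatter!r}")
        if self.d < 0 or self.g < 0 or self.s < 1:
            raise InvariantError("require d >= 0, g >= 0, s >= 1")
        if self.d >= 1 and self.g < 1:
            raise InvariantError("derivative order >= 1 requires gap >= 1")
        if self.d == 0 and self.g != 0:
            raise InvariantError("d = 0 requires g = 0")

    @property
    def code(self) -> str:
        return format_treatment(self)


def parse_treatment(code: str) -> PreprocessSpec:
    """Parse a printed treatment code like ``"SNV and Detrend 1,4,4"``."""
    m = re.fullmatch(r"\s*(.*?)\s+(\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*", code)
    if m is None:
        raise FormatError(f"malformed treatment code {code!r}; expected '<scatter> d,g,s'")
    name, d, g, s = m.group(1), int(m.group(2)), int(m.group(3)), int(m.group(4))
    try:
        scatter = _SCATTER_ALIASES[name.strip().lower()]
    except KeyError:
        raise FormatError(
            f"unknown scatter token {name!r} in {code!r} "
            f"(known: {sorted(set(_SCATTER_CANONICAL.values()))})"
        ) from None
    try:
        return PreprocessSpec(scatter=scatter, d=d, g=g, s=s)
    except InvariantError as exc:
        raise FormatError(f"invalid triple in {code!r}: {exc}") from None


def format_treatment(spec: PreprocessSpec) -> str:
    return f"{_SCATTER_CANONICAL[spec.scatter]} {spec.d},{spec.g},{spec.s}"


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_spectra(path, modality: str) -> SpectralDataset:
    """Read a wide spectra CSV: header ``sample_id,<axis values>``, numeric body."""
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a sample_id column plus at least one axis column")
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first header field must be 'sample_id', got {df.columns[0]!r}")
    try:
        axis = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric axis value in header ({exc})") from None
    body = df.iloc[:, 1:]
    bad = body.columns[body.isna().any(axis=0)]
    if len(bad):
        raise FormatError(f"{path}: missing/ragged values in column {bad[0]!r}")
    try:
        return SpectralDataset(list(df.iloc[:, 0]), axis, body.to_numpy(float), modality)
    except InvariantError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_spectra(ds: SpectralDataset, path) -> None:
    """Write the wide CSV at 6 significant digits."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("sample_id," + ",".join(_fmt(v) for v in ds.axis) + "\n")
        for sid, row in zip(ds.sample_ids, ds.signal):
            fh.write(sid + "," + ",".join(_fmt(v) for v in row) + "\n")


def _fmt(v: float) -> str:
    return f"{v:.6g}"


def read_reference(path) -> ReferenceTable:
    """Read a reference-chemistry CSV with ``name:unit`` headers.

    A row whose sample_id is ``SEL`` is interpreted as the per-analyte
    standard error of laboratory and stored as metadata.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first header field must be 'sample_id'")
    analytes, units = [], []
    for col in df.columns[1:]:
        if ":" not in col:
            raise FormatError(f"{path}: column {col!r} lacks a ':unit' suffix")
        name, unit = col.rsplit(":", 1)
        analytes.append(name.strip())
        try:
            units.append(_normalise_unit(unit))
        except FormatError as exc:
            raise FormatError(f"{path}: column {col!r}: {exc}") from None
    ids = list(df.iloc[:, 0])
    sel: dict[str, float] = {}
    if "SEL" in ids:
        i = ids.index("SEL")
        row = df.iloc[i, 1:].to_numpy(float)
        sel = {a: float(v) for a, v in zip(analytes, row) if np.isfinite(v)}
        df = df.drop(index=df.index[i])
        ids = list(df.iloc[:, 0])
    try:
        return ReferenceTable(ids, analytes, units, df.iloc[:, 1:].to_numpy(float), sel)
    except InvariantError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_reference(ref: ReferenceTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        cols = [f"{a}:{u}" for a, u in zip(ref.analytes, ref.units)]
        fh.write("sample_id," + ",".join(cols) + "\n")
        if ref.sel:
            fh.write("SEL," + ",".join(
                _fmt(ref.sel[a]) if a in ref.sel else "" for a in ref.analytes) + "\n")
        for sid, row in zip(ref.sample_ids, ref.values):
            fh.write(sid + "," + ",".join(_fmt(v) for v in row) + "\n")


def restrict_axis(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Keep columns with ``lo <= axis <= hi`` (order preserved)."""
    if not lo < hi:
        raise InvariantError(f"require lo < hi, got ({lo}, {hi})")
    keep = (ds.axis >= lo) & (ds.axis <= hi)
    if not keep.any():
        raise InvariantError(
            f"window ({lo}, {hi}) selects no points on axis spanning "
            f"[{ds.axis.min()}, {ds.axis.max()}]"
        )
    return SpectralDataset(ds.sample_ids, ds.axis[keep], ds.signal[:, keep], ds.modality)
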