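"""End-to-end pipeline: one shared calibration/validation split, a
pretreatment grid search per analyte x modality, external validation, and
the cross-technique SEPc comparison table.

The pipeline never lets validation samples influence model building: the
split happens first, the grid search and outlier elimination see only the
calibration subset, and the fitted pretreatment (including any MSC reference
mean) is frozen before the validation spectra are transformed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InvariantError
from .mpls import model_to_json
from .pipeline import (
    DEFAULT_TREATMENT_GRID,
    grid_search,
    split_calibration_validation,
)
from .preprocess import apply_pretreatment
from .simulate import default_scenario, generate_spectra, generate_concentrations
from .spectral_data import read_reference, read_spectra
from .validation import ValidationReport, external_validation, letter_display

log = logging.getLogger("milkcal")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compare_techniques"]

#: preferred technique order for tie-breaking in the letter display
_TECHNIQUE_ORDER = ("nir", "mir_atr", "sync_fluor")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    seed: int = 1
    fraction: float = 0.77
    t_max: int = 10
    n_groups: int = 4
    scale_residuals: bool = True
    alpha: float = 0.05
    t_threshold: float = 2.5
    h_threshold: float = 3.0
    passes: int = 2
    treatments: tuple[str, ...] = DEFAULT_TREATMENT_GRID
    analytes: tuple[str, ...] | None = None      # default: all in the reference
    modalities: tuple[str, ...] | None = None    # default: all spectra present
    axis_windows: dict = field(default_factory=dict)   # modality -> (lo, hi)
    spectra_paths: dict = field(default_factory=dict)  # modality -> CSV path
    reference_path: str | None = None
    scenario_n_samples: int = 242                # used when no paths given

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvariantError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.treatments = tuple(cfg.treatments)
        if cfg.analytes is not None:
            cfg.analytes = tuple(cfg.analytes)
        if cfg.modalities is not None:
            cfg.modalities = tuple(cfg.modalities)
        return cfg

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["treatments"] = list(self.treatments)
        if self.analytes is not None:
            d["analytes"] = list(self.analytes)
        if self.modalities is not None:
            d["modalities"] = list(self.modalities)
        return d


def _subseed(seed: int, stream: int) -> int:
    """Named sub-seed derived from the global seed (kept below 2**31)."""
    return int(np.random.SeedSequence([int(seed), stream]).generate_state(1)[0] % (2**31))


def _load_data(cfg: RunConfig):
    if cfg.reference_path or cfg.spectra_paths:
        if not (cfg.reference_path and cfg.spectra_paths):
            raise InvariantError("provide both reference_path and spectra_paths, or neither")
        ref = read_reference(cfg.reference_path)
        spectra = {m: read_spectra(p, m) for m, p in cfg.spectra_paths.items()}
        return ref, spectra
    scen = default_scenario(n_samples=cfg.scenario_n_samples, seed=_subseed(cfg.seed, 0))
    ref = generate_concentrations(scen)
    spectra = {m: generate_spectra(ref, scen, m) for m in sorted(scen.axes)}
    return ref, spectra


@dataclass
class AnalyteModalityResult:
    analyte: str
    modality: str
    treatment: str
    calibration: "object"            # CalibrationSummary
    validation: ValidationReport
    errors: np.ndarray               # per-sample validation errors (yhat - y)
    val_ids: tuple[str, ...]
    model_json: str


@dataclass
class PipelineResult:
    config: RunConfig
    cal_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    results: list[AnalyteModalityResult]
    manifest: dict

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            c, v = r.calibration, r.validation
            rows.append({
                "analyte": r.analyte, "technique": r.modality,
                "treatment": r.treatment, "n": c.n_used,
                "outliers": c.n_outliers, "T": c.T,
                "SEC": c.sec, "R2C": c.r2c, "SECV": c.secv, "R2CV": c.r2cv,
                "n_val": v.n, "SEP": v.sep, "R2V": v.r2v,
                "bias": v.bias, "SEPc": v.sepc,
                "bias_significant": v.bias_significant,
            })
        return pd.DataFrame(rows)


def _run_one(ds_cal, ds_val, y_cal, y_val, analyte, modality, cfg: RunConfig):
    window = cfg.axis_windows.get(modality)
    grid = grid_search(
        ds_cal, y_cal, cfg.treatments, T_max=cfg.t_max, n_groups=cfg.n_groups,
        seed=_subseed(cfg.seed, 2), scale_residuals=cfg.scale_residuals,
        axis_window=tuple(window) if window else None,
    )
    best = grid.best
    treated_val = apply_pretreatment(ds_val, best.pretreatment)
    from .mpls import predict
    y_hat = predict(best.result.model, treated_val.signal)
    report = external_validation(y_val, y_hat, alpha=cfg.alpha)
    log.info(
        "%s / %s: treatment=%s T=%d R2CV=%.3f SEP=%.4g",
        analyte, modality, grid.selected, best.summary.T,
        best.summary.r2cv, report.sep,
    )
    return AnalyteModalityResult(
        analyte=analyte, modality=modality, treatment=grid.selected,
        calibration=best.summary, validation=report,
        errors=np.asarray(y_hat) - np.asarray(y_val),
        val_ids=tuple(ds_val.sample_ids),
        model_json=model_to_json(best.result.model),
    )


def run_pipeline(cfg: RunConfig, out_dir=None) -> PipelineResult:
    """Run the full calibration/validation pipeline described by ``cfg``.

    One random split is shared by every modality; each analyte x modality
    cell runs the pretreatment grid search with two-pass outlier elimination
    and is then validated externally.  When ``out_dir`` is given, report
    CSVs, model JSONs and a run manifest are written there.
    """
    ref, spectra = _load_data(cfg)
    modalities = tuple(cfg.modalities) if cfg.modalities else tuple(spectra)
    missing = [m for m in modalities if m not in spectra]
    if missing:
        raise InvariantError(f"no spectra for modalities {missing}")
    analytes = tuple(cfg.analytes) if cfg.analytes else ref.analytes
    absent = [a for a in analytes if a not in ref.analytes]
    if absent:
        raise InvariantError(f"analytes absent from reference table: {absent}")

    common = [s for s in ref.sample_ids
              if all(s in spectra[m].sample_ids for m in modalities)]
    log.info("pipeline: %d common samples, %d analytes, %d modalities",
             len(common), len(analytes), len(modalities))
    cal_ids, val_ids = split_calibration_validation(
        common, cfg.fraction, _subseed(cfg.seed, 1)
    )
    log.info("split: %d calibration / %d validation samples", len(cal_ids), len(val_ids))

    results = []
    for analyte in analytes:
        y_cal = ref.subset(cal_ids).column(analyte)
        y_val = ref.subset(val_ids).column(analyte)
        for modality in modalities:
            ds_cal = spectra[modality].subset(cal_ids)
            ds_val = spectra[modality].subset(val_ids)
            results.append(
                _run_one(ds_cal, ds_val, y_cal, y_val, analyte, modality, cfg)
            )

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seeds": {"simulation": _subseed(cfg.seed, 0),
                  "split": _subseed(cfg.seed, 1),
                  "cross_validation": _subseed(cfg.seed, 2)},
        "n_calibration": len(cal_ids), "n_validation": len(val_ids),
        "selected_treatments": {
            f"{r.analyte}|{r.modality}": r.treatment for r in results
        },
    }
    result = PipelineResult(cfg, tuple(cal_ids), tuple(val_ids), results, manifest)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _fmt2(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: f"{v:.2f}")
    return out


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    df = result.report_frame()
    _fmt2(df).to_csv(out_dir / "report.csv", index=False)
    df.to_csv(out_dir / "report_full.csv", index=False, float_format="%.17g")
    comparison = compare_techniques(result)
    comparison.to_csv(out_dir / "comparison.csv", index=False)
    models = out_dir / "models"
    models.mkdir(exist_ok=True)
    for r in result.results:
        safe = f"{r.analyte}_{r.modality}".replace("/", "-").replace(":", "-")
        (models / f"{safe}.json").write_text(r.model_json)
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    log.info("wrote report to %s", out_dir)


def compare_techniques(result: PipelineResult, alpha: float | None = None) -> pd.DataFrame:
    """Per-analyte cross-technique SEPc table with compact letters.

    Techniques on the same analyte line sharing a letter have SEPc values
    that the paired variance test cannot distinguish at ``alpha``; a ``*``
    marks a bias significantly different from zero.
    """
    alpha = result.config.alpha if alpha is None else alpha
    rows = []
    by_analyte: dict[str, list[AnalyteModalityResult]] = {}
    for r in result.results:
        by_analyte.setdefault(r.analyte, []).append(r)
    for analyte, cells in by_analyte.items():
        ids0 = cells[0].val_ids
        if any(c.val_ids != ids0 for c in cells):
            raise InvariantError(
                f"validation sets differ across techniques for {analyte!r}"
            )
        errors = {c.modality: c.errors for c in cells}
        order = tuple(m for m in _TECHNIQUE_ORDER if m in errors) + tuple(
            m for m in errors if m not in _TECHNIQUE_ORDER
        )
        letters = letter_display(errors, alpha=alpha, order=order)
        row: dict = {"analyte": analyte}
        for c in cells:
            star = "*" if c.validation.bias_significant else ""
            row[f"bias_{c.modality}"] = f"{c.validation.bias:.4g}{star}"
            row[f"SEPc_{c.modality}"] = f"{c.validation.sepc:.4g} {letters[c.modality]}"
        rows.append(row)
    return pd.DataFrame(rows)
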