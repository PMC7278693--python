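"""Model-building loop: split, 4-group cross-validation, term selection,
two-pass T/H outlier elimination and the pretreatment grid search.

Conventions (deliberate, and the ones the statistics below assume):

* SECV pools all held-out cross-validation residuals into one error per term
  count, ``sqrt(sum(e^2) / n)`` with no degrees-of-freedom correction.
* SEC on the final calibration fit uses ``sqrt(sum(e^2) / (n - T - 1))``.
* R^2 is always ``1 - SSE/SST`` (never a squared correlation).
* A concentration outlier (reason ``T_residual``) is a calibration residual
  beyond 2.5 * SEC; a spectral outlier (reason ``H_distance``) has
  standardized Mahalanobis distance GH > 3.  At most two elimination passes
  run, each refitting with a freshly cross-validated term count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import FitError, InvariantError, MilkcalError
from .mpls import MplsModel, fit_mpls, gh_distance, predict
from .preprocess import FittedPretreatment, apply_pretreatment, fit_pretreatment
from .spectral_data import PreprocessSpec, SpectralDataset, parse_treatment

__all__ = [
    "DEFAULT_TREATMENT_GRID",
    "CvResult",
    "CalibrationSummary",
    "EliminationResult",
    "GridEntry",
    "GridResult",
    "split_calibration_validation",
    "cross_validate",
    "eliminate_outliers",
    "grid_search",
]

#: every distinct pretreatment code printed in the source tables, in first
#: appearance order ("MSC" and "Standard MSC" are the same method).
DEFAULT_TREATMENT_GRID: tuple[str, ...] = (
    "None 1,4,4", "None 2,4,4", "SNV and Detrend 0,0,1", "SNV and Detrend 1,4,4",
    "None 1,20,20", "None 0,0,1", "SNV and Detrend 1,30,30", "Weighted MSC 0,0,1",
    "None 2,10,10", "Detrend 0,0,1", "SNV and Detrend 2,8,8", "Standard MSC 1,4,4",
    "Detrend 1,8,8", "None 2,20,20", "None 1,8,8", "Standard MSC 0,0,1",
    "SNV and Detrend 2,10,10", "None 2,8,8", "Inverse MSC 0,0,1",
    "SNV and Detrend 1,20,20", "Detrend 1,4,4", "SNV and Detrend 1,8,8",
    "Inverse MSC 2,8,8", "SNV 2,10,10", "SNV 1,8,8", "SNV 1,4,4",
    "SNV and Detrend 2,30,30", "None 2,16,16", "Detrend 1,1,4", "SNV 2,30,30",
    "SNV 1,30,30", "Weighted MSC 1,4,4", "Standard MSC 2,10,10",
    "Weighted MSC 2,8,8", "SNV 0,0,1", "None 2,30,30",
)


def split_calibration_validation(ids, fraction: float, seed: int):
    """Random disjoint, exhaustive calibration/validation split.

    ``round(fraction * n)`` ids go to calibration; original input order is
    preserved within each set.  Deterministic under ``seed``.
    """
    ids = [str(s) for s in ids]
    if len(set(ids)) != len(ids):
        raise InvariantError("ids must be unique")
    if not 0.0 < fraction < 1.0:
        raise InvariantError(f"fraction must be in (0, 1), got {fraction}")
    n = len(ids)
    if n < 8:
        raise InvariantError(f"need at least 8 samples to split, got {n}")
    n_cal = int(math.floor(fraction * n + 0.5))
    n_cal = min(max(n_cal, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal_idx = set(perm[:n_cal].tolist())
    cal = [s for i, s in enumerate(ids) if i in cal_idx]
    val = [s for i, s in enumerate(ids) if i not in cal_idx]
    return cal, val


@dataclass(frozen=True)
class CvResult:
    """SECV/R2CV curves over 1..T_hi terms and the chosen term count."""

    secv: np.ndarray     # (T_hi,), secv[t-1] is SECV with t terms
    r2cv: np.ndarray     # (T_hi,)
    chosen_T: int
    groups: tuple[tuple[int, ...], ...]  # index groups, for audit

    @property
    def chosen_secv(self) -> float:
        return float(self.secv[self.chosen_T - 1])

    @property
    def chosen_r2cv(self) -> float:
        return float(self.r2cv[self.chosen_T - 1])


def _fit_capped(X, y, T, scale_residuals) -> tuple[MplsModel, np.ndarray, int]:
    """Fit with at most T terms, backing off when the residual rank runs out."""
    T = min(T, X.shape[0] - 1, X.shape[1])
    while True:
        try:
            model, fitted = fit_mpls(X, y, T, scale_residuals)
            return model, fitted, T
        except FitError:
            if T <= 1:
                raise
            T -= 1


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    T_max: int,
    n_groups: int = 4,
    seed: int = 0,
    scale_residuals: bool = True,
) -> CvResult:
    """Randomized contiguous-block cross-validation over term counts.

    The sample order is permuted under ``seed`` and cut into ``n_groups``
    blocks as equal as possible; each block is held out once and predicted
    from a model fitted on the rest.  Held-out residuals are pooled per term
    count; the chosen T minimises SECV (smallest T on ties).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if T_max < 1:
        raise InvariantError("T_max must be >= 1")
    if n < 2 * n_groups:
        raise FitError(f"need at least {2 * n_groups} samples for {n_groups}-group CV")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    groups = [g for g in np.array_split(perm, n_groups)]
    if min(len(g) for g in groups) < 2:
        raise FitError("cross-validation group with fewer than 2 samples")

    T_hi = T_max
    fold_pred = []  # (held_out_idx, (T_f, n_held) prediction matrix)
    for g in groups:
        mask = np.ones(n, dtype=bool)
        mask[g] = False
        model, _, T_f = _fit_capped(X[mask], y[mask], T_max, scale_residuals)
        T_hi = min(T_hi, T_f)
        preds = np.stack([predict(model, X[g], n_terms=t) for t in range(1, T_f + 1)])
        fold_pred.append((g, preds))

    sse = np.zeros(T_hi)
    for g, preds in fold_pred:
        e = preds[:T_hi] - y[g][None, :]
        sse += (e ** 2).sum(axis=1)
    secv = np.sqrt(sse / n)
    sst = float(((y - y.mean()) ** 2).sum())
    r2cv = 1.0 - sse / sst
    # smallest T within numerical tolerance of the SECV minimum, so exact-fit
    # data does not inflate T on floating-point ties
    lo = secv.min()
    chosen = int(np.flatnonzero(secv <= lo + 1e-12 + 1e-6 * lo)[0]) + 1
    return CvResult(secv=secv, r2cv=r2cv, chosen_T=chosen,
                    groups=tuple(tuple(int(i) for i in g) for g in groups))


@dataclass(frozen=True)
class OutlierRecord:
    sample_id: str
    pass_index: int
    reason: str  # "T_residual" or "H_distance"


@dataclass(frozen=True)
class CalibrationSummary:
    n_used: int
    n_outliers: int
    T: int
    sec: float
    r2c: float
    secv: float
    r2cv: float
    outlier_log: tuple[OutlierRecord, ...] = ()
    treatment: str | None = None


@dataclass(frozen=True)
class EliminationResult:
    kept_ids: tuple[str, ...]
    summary: CalibrationSummary
    model: MplsModel
    cv: CvResult


def _sec(e: np.ndarray, T: int) -> float:
    n = e.size
    if n <= T + 1:
        raise FitError(f"SEC undefined: n = {n} <= T + 1 = {T + 1}")
    return float(np.sqrt((e ** 2).sum() / (n - T - 1)))


def eliminate_outliers(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids,
    T_max: int,
    n_groups: int = 4,
    seed: int = 0,
    scale_residuals: bool = True,
    t_threshold: float = 2.5,
    h_threshold: float = 3.0,
    max_passes: int = 2,
) -> EliminationResult:
    """Two-pass concentration (T) and spectral (H) outlier elimination.

    Each pass cross-validates the term count on the current set, fits the
    full calibration model, flags samples with |residual| > 2.5 * SEC
    (``T_residual``) or GH > 3 (``H_distance``), removes them and refits.
    The loop stops early when a pass flags nothing; it never runs more than
    ``max_passes`` flagging passes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    sample_ids = tuple(str(s) for s in sample_ids)
    if len(sample_ids) != X.shape[0] or y.size != X.shape[0]:
        raise InvariantError("X, y and sample_ids must be aligned")
    n0 = X.shape[0]
    if n0 < 10:
        raise FitError(f"outlier elimination needs at least 10 samples, got {n0}")

    kept = np.arange(n0)
    log: list[OutlierRecord] = []
    for pass_index in range(1, max_passes + 1):
        cv = cross_validate(X[kept], y[kept], T_max, n_groups, seed, scale_residuals)
        model, fitted, T = _fit_capped(X[kept], y[kept], cv.chosen_T, scale_residuals)
        e = y[kept] - fitted
        sec = _sec(e, T)
        gh = gh_distance(model, X[kept])
        t_flag = np.abs(e) > t_threshold * sec
        h_flag = gh > h_threshold
        flagged = t_flag | h_flag
        if not flagged.any():
            break
        n_left = kept.size - int(flagged.sum())
        if n_left < max(T + 2, 6):
            raise FitError(
                f"removing {int(flagged.sum())} outliers would leave {n_left} samples "
                f"(< {max(T + 2, 6)})"
            )
        for i in np.flatnonzero(flagged):
            sid = sample_ids[kept[i]]
            if t_flag[i]:
                log.append(OutlierRecord(sid, pass_index, "T_residual"))
            if h_flag[i]:
                log.append(OutlierRecord(sid, pass_index, "H_distance"))
        kept = kept[~flagged]

    cv = cross_validate(X[kept], y[kept], T_max, n_groups, seed, scale_residuals)
    model, fitted, T = _fit_capped(X[kept], y[kept], cv.chosen_T, scale_residuals)
    e = y[kept] - fitted
    sst = float(((y[kept] - y[kept].mean()) ** 2).sum())
    summary = CalibrationSummary(
        n_used=int(kept.size),
        n_outliers=n0 - int(kept.size),
        T=T,
        sec=_sec(e, T),
        r2c=1.0 - float((e ** 2).sum()) / sst,
        secv=float(cv.secv[min(T, cv.secv.size) - 1]),
        r2cv=float(cv.r2cv[min(T, cv.r2cv.size) - 1]),
        outlier_log=tuple(log),
    )
    return EliminationResult(
        kept_ids=tuple(sample_ids[i] for i in kept),
        summary=summary, model=model, cv=cv,
    )


@dataclass(frozen=True)
class GridEntry:
    spec: PreprocessSpec
    pretreatment: FittedPretreatment
    result: EliminationResult

    @property
    def summary(self) -> CalibrationSummary:
        return self.result.summary


@dataclass(frozen=True)
class GridResult:
    entries: tuple[GridEntry, ...]
    failures: tuple[tuple[str, str], ...]  # (code, error message)
    selected: str                          # treatment code of the winner

    @property
    def best(self) -> GridEntry:
        for e in self.entries:
            if e.spec.code == self.selected:
                return e
        raise KeyError(self.selected)

    def summaries(self) -> dict[str, CalibrationSummary]:
        return {e.spec.code: e.summary for e in self.entries}


def grid_search(
    ds: SpectralDataset,
    y: np.ndarray,
    treatments,
    T_max: int = 10,
    n_groups: int = 4,
    seed: int = 0,
    scale_residuals: bool = True,
    axis_window: tuple[float, float] | None = None,
) -> GridResult:
    """Run pretreat -> outlier elimination -> summary for each treatment and
    select the winner: highest R2CV, ties broken by lower SECV then input
    order.  Treatments whose preconditions fail are recorded and skipped.
    """
    specs = [parse_treatment(t) if isinstance(t, str) else t for t in treatments]
    if not specs:
        raise InvariantError("at least one treatment required")
    if axis_window is not None:
        specs = [
            PreprocessSpec(s.scatter, s.d, s.g, s.s, axis_window) for s in specs
        ]
    entries: list[GridEntry] = []
    failures: list[tuple[str, str]] = []
    for spec in specs:
        try:
            fp = fit_pretreatment(ds, spec)
            treated = apply_pretreatment(ds, fp)
            res = eliminate_outliers(
                treated.signal, y, ds.sample_ids, T_max, n_groups, seed,
                scale_residuals,
            )
            res = EliminationResult(
                res.kept_ids,
                CalibrationSummary(**{**res.summary.__dict__, "treatment": spec.code}),
                res.model, res.cv,
            )
            entries.append(GridEntry(spec, fp, res))
        except MilkcalError as exc:
            failures.append((spec.code, str(exc)))
    if not entries:
        raise FitError(
            "all treatments failed: " + "; ".join(f"{c}: {m}" for c, m in failures)
        )
    best = max(
        range(len(entries)),
        key=lambda i: (entries[i].summary.r2cv, -entries[i].summary.secv, -i),
    )
    return GridResult(tuple(entries), tuple(failures), entries[best].spec.code)
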