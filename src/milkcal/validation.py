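"""External-validation statistics and paired model comparisons.

For validation errors ``e = y_hat - y`` on ``n`` samples:

* ``bias = mean(e)``
* ``SEP  = sqrt(sum(e^2) / n)``             (bias included, denominator n)
* ``SEPc = sqrt(sum((e - bias)^2) / (n-1))``  (bias-corrected, denominator n-1)

which gives the exact decomposition ``SEP^2 = bias^2 + SEPc^2 * (n-1)/n``.
The bias is tested against zero with a one-sample t on the errors; two
models validated on the *same* samples are compared on SEPc with the
Pitman-Morgan paired variance test (the construction behind Fearn's SEP
comparison): with ``s = e1 + e2`` and ``d = e1 - e2``, the correlation of
``s`` and ``d`` is zero exactly when the two error variances are equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, InvariantError
from .spectral_data import ReferenceTable

__all__ = [
    "ValidationReport",
    "SepComparison",
    "external_validation",
    "bias_test",
    "fearn_test",
    "correlation_matrix",
    "letter_display",
]


@dataclass(frozen=True)
class ValidationReport:
    n: int
    sep: float
    r2v: float
    bias: float
    sepc: float
    bias_t: float
    bias_p: float
    bias_significant: bool
    alpha: float


@dataclass(frozen=True)
class SepComparison:
    statistic: float
    p_value: float
    significant: bool
    n: int
    labels: tuple[str, str]


def external_validation(y_true, y_pred, alpha: float = 0.05) -> ValidationReport:
    """SEP/R2V/bias/SEPc on a validation set, with the bias test attached."""
    y = np.asarray(y_true, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    if y.shape != yh.shape or y.ndim != 1:
        raise InvariantError("y_true and y_pred must be equal-length vectors")
    n = y.size
    if n < 3:
        raise InvariantError(f"external validation needs n >= 3, got {n}")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise FitError("R2V undefined: validation reference values have zero variance")
    e = yh - y
    bias = float(e.mean())
    sep = float(np.sqrt((e ** 2).sum() / n))
    sepc = float(np.sqrt(((e - bias) ** 2).sum() / (n - 1)))
    r2v = 1.0 - float((e ** 2).sum()) / sst
    t, p, sig = bias_test(bias, sepc, n, alpha)
    return ValidationReport(n=n, sep=sep, r2v=r2v, bias=bias, sepc=sepc,
                            bias_t=t, bias_p=p, bias_significant=sig, alpha=alpha)


def bias_test(bias: float, sepc: float, n: int, alpha: float = 0.05):
    """One-sample t test of the mean prediction error against zero.

    ``t = bias / (SEPc / sqrt(n))`` with n-1 degrees of freedom, two-sided.
    Returns ``(t, p, significant)``.
    """
    if n < 2:
        raise InvariantError(f"bias test needs n >= 2, got {n}")
    if sepc < 0:
        raise InvariantError("SEPc must be nonnegative")
    if sepc == 0:
        if bias == 0:
            return 0.0, 1.0, False
        return float(np.sign(bias) * np.inf), 0.0, True
    t = bias / (sepc / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return float(t), p, bool(p <= alpha)


def fearn_test(
    e1,
    e2,
    alpha: float = 0.05,
    bias_correct: bool = True,
    labels: tuple[str, str] = ("model_1", "model_2"),
) -> SepComparison:
    """Pitman-Morgan paired comparison of two error variances (SEPc's).

    ``e1`` and ``e2`` must be prediction errors on the same validation
    samples, in the same order.  With ``bias_correct`` each vector is centred
    first, so the test compares SEPc exactly.  Degenerate inputs (equal
    vectors, or a zero-variance sum/difference) yield p = 1 by convention.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape or e1.ndim != 1:
        raise InvariantError("paired error vectors must be equal-length")
    n = e1.size
    if n < 4:
        raise InvariantError(f"paired variance test needs n >= 4, got {n}")
    if bias_correct:
        e1 = e1 - e1.mean()
        e2 = e2 - e2.mean()
    s = e1 + e2
    d = e1 - e2
    if s.std() == 0 or d.std() == 0:
        return SepComparison(0.0, 1.0, False, n, labels)
    r = float(np.corrcoef(s, d)[0, 1])
    if abs(r) >= 1.0:
        return SepComparison(float(np.sign(r) * np.inf), 0.0, True, n, labels)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return SepComparison(float(t), p, bool(p <= alpha), n, labels)


def correlation_matrix(ref: ReferenceTable) -> pd.DataFrame:
    """Pearson correlations between analytes (pairwise complete, here always
    complete since the table admits no missing values).

    Zero-variance analytes yield NaN entries off the diagonal rather than a
    silent zero; the diagonal is exactly 1.
    """
    if ref.n_samples < 3:
        raise InvariantError("correlation matrix needs at least 3 samples")
    df = ref.to_dataframe()
    sd = df.std(ddof=1)
    corr = df.corr(method="pearson")
    for a in df.columns[sd == 0]:
        corr.loc[a, :] = np.nan
        corr.loc[:, a] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


def letter_display(
    errors: dict[str, np.ndarray],
    alpha: float = 0.05,
    order: tuple[str, ...] | None = None,
) -> dict[str, str]:
    """Compact letter display from pairwise Pitman-Morgan tests.

    Methods sharing a letter are not significantly different at ``alpha``.
    Letters are assigned in ascending SEPc order; ``order`` fixes the
    tie-break ranking of methods with identical SEPc (input order otherwise).
    """
    names = list(errors)
    if order:
        names.sort(key=lambda m: order.index(m) if m in order else len(order))
    if len(names) < 2:
        return {m: "a" for m in names}
    sepc = {
        m: float(np.sqrt(((e - np.mean(e)) ** 2).sum() / (len(e) - 1)))
        for m, e in ((m, np.asarray(errors[m], float)) for m in names)
    }
    differs = {
        frozenset((a, b)): fearn_test(errors[a], errors[b], alpha, labels=(a, b)).significant
        for i, a in enumerate(names) for b in names[i + 1:]
    }
    rank = {m: i for i, m in enumerate(sorted(names, key=lambda m: sepc[m]))}
    # maximal cliques of the "not significantly different" graph (the method
    # count is tiny, so brute force over subsets is exact)
    k = len(names)
    cliques: list[tuple[str, ...]] = []
    for mask in range(1, 1 << k):
        members = [names[i] for i in range(k) if mask >> i & 1]
        if any(differs[frozenset((a, b))]
               for i, a in enumerate(members) for b in members[i + 1:]):
            continue
        cliques.append(tuple(members))
    maximal = [c for c in cliques
               if not any(set(c) < set(o) for o in cliques)]
    maximal.sort(key=lambda c: min(rank[m] for m in c))
    letters = {m: "" for m in names}
    for c, letter in zip(maximal, "abcdefghijklmnopqrstuvwxyz"):
        for m in c:
            letters[m] += letter
    return {m: "".join(sorted(letters[m])) for m in names}
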