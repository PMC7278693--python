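"""Modified partial least squares (PLS1 with per-factor residual scaling).

The only difference between MPLS and standard PLS1 here is the
``scale_residuals`` flag: after each latent factor is extracted and the
spectral matrix deflated, every residual column is divided by its standard
deviation (floored so dead spectral regions cannot blow up).  The scaling
vectors are stored so prediction replays the exact same linear map.  With
the flag off the model is plain NIPALS PLS1.

The standardized Mahalanobis distance GH of a spectrum is its squared
Mahalanobis distance in latent-score space divided by the number of factors,
so an average calibration sample scores near 1 and the customary threshold
of 3 flags spectral outliers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, InvariantError

__all__ = ["MplsModel", "fit_mpls", "predict", "gh_distance", "model_to_json", "model_from_json"]

_SD_FLOOR = 1e-10


@dataclass(frozen=True)
class MplsModel:
    """Fitted PLS1/MPLS model on pretreated, centred spectra."""

    x_mean: np.ndarray            # (p,)
    y_mean: float
    n_terms: int                  # T
    weights: np.ndarray           # (T, p) unit-norm NIPALS weights
    x_loadings: np.ndarray        # (T, p)
    y_loadings: np.ndarray        # (T,)
    scalings: np.ndarray          # (T, p) residual sds applied after each factor
    regression_vector: np.ndarray # (p,) coefficients on centred pretreated spectra
    coef_per_terms: np.ndarray    # (T, p) regression vector truncated at 1..T factors
    score_mean: np.ndarray        # (T,)
    score_cov_inv: np.ndarray     # (T, T)
    scale_residuals: bool = True
    meta: dict = field(default_factory=dict)  # pretreatment code, axis window, ...

    @property
    def n_points(self) -> int:
        return self.x_mean.size


def _nipals(X: np.ndarray, y: np.ndarray, T: int, scale_residuals: bool):
    """Run NIPALS PLS1, returning per-factor arrays, scores and the running
    coefficient map.

    ``A`` tracks the linear map from the centred input row-space to the
    deflated row-space, so coefficients on the *original* centred spectra
    fall out as q_a * (A_a w_a) summed over factors.
    """
    n, p = X.shape
    Xc = X.copy()
    yc = y.copy()
    W = np.zeros((T, p))
    P = np.zeros((T, p))
    Q = np.zeros(T)
    S = np.ones((T, p))
    scores = np.zeros((n, T))
    coef_per_terms = np.zeros((T, p))
    A = np.eye(p)
    b = np.zeros(p)
    for a in range(T):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            raise FitError(
                f"no spectral variance left for factor {a + 1}; reduce the number of terms"
            )
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-28:
            raise FitError(f"degenerate score vector at factor {a + 1}")
        pl = Xc.T @ t / tt
        q = float(yc @ t) / tt
        Xc -= np.outer(t, pl)
        yc = yc - q * t
        W[a], P[a], Q[a] = w, pl, q
        scores[:, a] = t
        b = b + q * (A @ w)
        coef_per_terms[a] = b
        if scale_residuals:
            sd = Xc.std(axis=0, ddof=1) if n > 1 else np.zeros(p)
            sd = np.maximum(sd, _SD_FLOOR)
            Xc /= sd
            S[a] = sd
            A = (A - np.outer(A @ w, pl)) / sd
        else:
            A = A - np.outer(A @ w, pl)
    return W, P, Q, S, scores, b, coef_per_terms


def fit_mpls(
    X: np.ndarray,
    y: np.ndarray,
    T: int,
    scale_residuals: bool = True,
    meta: dict | None = None,
) -> tuple[MplsModel, np.ndarray]:
    """Fit on pretreated spectra; returns (model, fitted calibration values)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise InvariantError("X must be (n, p) and y (n,) with matching n")
    n, p = X.shape
    if n < 3:
        raise FitError(f"need at least 3 calibration samples, got {n}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InvariantError("missing values in calibration data")
    if not 1 <= T <= min(n - 1, p):
        raise FitError(f"T = {T} outside [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if y.std() == 0:
        raise FitError("reference values have zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, Q, S, scores, b, coef_per_terms = _nipals(
        X - x_mean, y - y_mean, T, scale_residuals
    )
    score_mean = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False, ddof=1).reshape(T, T)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        raise FitError(
            "singular latent-score covariance; reduce the number of terms"
        ) from None
    model = MplsModel(
        x_mean=x_mean, y_mean=y_mean, n_terms=T,
        weights=W, x_loadings=P, y_loadings=Q, scalings=S,
        regression_vector=b, coef_per_terms=coef_per_terms,
        score_mean=score_mean, score_cov_inv=cov_inv,
        scale_residuals=scale_residuals, meta=dict(meta or {}),
    )
    return model, predict(model, X)


def _check_X(model: MplsModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    one = X.ndim == 1
    if one:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != model.n_points:
        raise InvariantError(
            f"spectra have {X.shape[-1]} points; model expects {model.n_points}"
        )
    return X


def predict(model: MplsModel, X: np.ndarray, n_terms: int | None = None) -> np.ndarray:
    """Predict concentrations; ``n_terms`` truncates the model to fewer factors."""
    X = _check_X(model, X)
    T = model.n_terms if n_terms is None else int(n_terms)
    if not 1 <= T <= model.n_terms:
        raise InvariantError(f"n_terms must be in [1, {model.n_terms}]")
    b = model.regression_vector if T == model.n_terms else model.coef_per_terms[T - 1]
    return model.y_mean + (X - model.x_mean) @ b


def scores(model: MplsModel, X: np.ndarray) -> np.ndarray:
    """Latent scores of new spectra, replaying deflation and residual scaling."""
    X = _check_X(model, X)
    Xc = X - model.x_mean
    out = np.zeros((X.shape[0], model.n_terms))
    for a in range(model.n_terms):
        t = Xc @ model.weights[a]
        out[:, a] = t
        Xc = (Xc - np.outer(t, model.x_loadings[a])) / model.scalings[a]
    return out


def gh_distance(model: MplsModel, X: np.ndarray) -> np.ndarray:
    """Standardized Mahalanobis distance GH = D^2 / T in latent-score space."""
    t = scores(model, X) - model.score_mean
    d2 = np.einsum("ij,jk,ik->i", t, model.score_cov_inv, t)
    return d2 / model.n_terms


# ---------------------------------------------------------------------------
# JSON round-trip (binary64 via repr -> 17 significant digits)
# ---------------------------------------------------------------------------

def model_to_json(model: MplsModel) -> str:
    def arr(a):
        return np.asarray(a).tolist()
    payload = {
        "x_mean": arr(model.x_mean), "y_mean": model.y_mean,
        "n_terms": model.n_terms, "weights": arr(model.weights),
        "x_loadings": arr(model.x_loadings), "y_loadings": arr(model.y_loadings),
        "scalings": arr(model.scalings),
        "regression_vector": arr(model.regression_vector),
        "coef_per_terms": arr(model.coef_per_terms),
        "score_mean": arr(model.score_mean), "score_cov_inv": arr(model.score_cov_inv),
        "scale_residuals": model.scale_residuals, "meta": model.meta,
    }
    return json.dumps(payload)


def model_from_json(text: str) -> MplsModel:
    d = json.loads(text)
    return MplsModel(
        x_mean=np.array(d["x_mean"]), y_mean=d["y_mean"], n_terms=d["n_terms"],
        weights=np.array(d["weights"]), x_loadings=np.array(d["x_loadings"]),
        y_loadings=np.array(d["y_loadings"]), scalings=np.array(d["scalings"]),
        regression_vector=np.array(d["regression_vector"]),
        coef_per_terms=np.array(d["coef_per_terms"]),
        score_mean=np.array(d["score_mean"]), score_cov_inv=np.array(d["score_cov_inv"]),
        scale_residuals=d["scale_residuals"], meta=d.get("meta", {}),
    )
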