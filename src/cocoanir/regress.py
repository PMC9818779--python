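"""Calibration engines: PLS (NIPALS), modified PLS and PCR.

All three engines regress a single constituent *y* on centered spectra
*X*. Spectra are column-centered but never variance-scaled globally (the
usual convention for NIR absorbance data); *y* is centered only.

* **PLS** — univariate-response NIPALS with per-factor deflation of both
  X and y.
* **MPLS** — the Shenk-Westerhaus "modified" PLS used by NIR calibration
  suites: identical to NIPALS except that after each factor's deflation
  the residual matrix columns are standardized by their per-wavelength
  residual SD before the next factor is extracted. The accumulated
  scalings are folded back into the final regression vector, so
  prediction needs only the raw processed spectrum.
* **PCR** — ordinary least squares of y on the first k principal-component
  scores of centered X.

Every engine exposes a *coefficient path*: regression vectors for factor
counts 0..k from a single decomposition, which makes cross-validated
factor selection cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import DataValidationError, DegenerateDataError
from .preprocess import MathTreatment

METHODS = ("PLS", "MPLS", "PCR")

#: hard cap on extractable factors for n calibration samples
def max_factors(n_samples: int, n_wavelengths: int | None = None) -> int:
    """Factor-count cap: min(16, n-6), further limited by the grid size.

    Prevents overfit at the ~50-sample scale these calibrations run at.
    """
    cap = min(16, n_samples - 6)
    if n_wavelengths is not None:
        cap = min(cap, n_wavelengths)
    return max(cap, 1)


@dataclass
class CalibrationModel:
    """A fitted calibration: everything needed to predict new spectra.

    Prediction is ``y_mean + (x - x_mean) @ coefficients`` for spectra on
    the model's retained wavelength grid, processed with the model's
    treatment (using the stored MSC reference where applicable).
    """

    method: str
    constituent: str | None
    treatment: Optional[MathTreatment]
    n_factors: int
    wavelengths: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray
    loadings: np.ndarray | None = None
    scores_variance: np.ndarray | None = None
    msc_reference: np.ndarray | None = None
    training_stats: dict | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


@dataclass
class _Path:
    """Coefficient path from one decomposition: B[k] is the regression
    vector using k factors (B[0] = 0, i.e. mean-only model)."""

    x_mean: np.ndarray
    y_mean: float
    B: np.ndarray            # (achieved+1, p)
    loadings: np.ndarray     # (achieved, p)
    scores_variance: np.ndarray
    achieved: int

    def predict(self, X: np.ndarray, k: int) -> np.ndarray:
        k = min(k, self.achieved)
        return self.y_mean + (np.asarray(X, float) - self.x_mean) @ self.B[k]


def _check_xy(X: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise DataValidationError("X must be 2-D (samples x wavelengths)")
    if y.size != X.shape[0]:
        raise DataValidationError("X and y have different sample counts")
    if k < 0:
        raise DataValidationError("factor count must be >= 0")
    if k > 0 and X.shape[0] < k + 2:
        raise DataValidationError(
            f"need at least k+2 = {k + 2} samples for {k} factors, have {X.shape[0]}"
        )
    return X, y


def _pls_path(X: np.ndarray, y: np.ndarray, max_k: int, modified: bool) -> _Path:
    """NIPALS decomposition with optional per-factor residual standardization.

    The MPLS scalings are folded back so every B[k] applies to raw
    (processed, uncentered-by-caller) spectra.
    """
    X, y = _check_xy(X, y, max_k)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean
    y_scale = max(float(np.abs(yr).max(initial=0.0)), 1e-30)

    B = np.zeros((max_k + 1, p))
    W: list[np.ndarray] = []
    P: list[np.ndarray] = []
    Q: list[float] = []
    scales: list[np.ndarray | None] = []  # scaling applied before factor a
    tvar: list[float] = []
    achieved = 0

    for a in range(max_k):
        if modified and a > 0:
            sd = Xr.std(axis=0, ddof=1)
            # residual columns already explained are frozen at scale 1
            sd = np.where(sd < 1e-12, 1.0, sd)
            Xr = Xr / sd
            scales.append(sd)
        else:
            scales.append(None)
        if float(np.linalg.norm(yr)) <= 1e-10 * y_scale:
            # y fully explained: a perfect fit, not a rank failure -- the
            # path simply stays flat for larger factor counts
            B[a + 1: max_k + 1] = B[a]
            achieved = max_k
            break
        c = Xr.T @ yr
        nc = float(np.linalg.norm(c))
        if nc < 1e-12 * y_scale * max(1.0, float(np.abs(Xr).max(initial=0.0))):
            break  # covariance exhausted: rank limit reached
        w = c / nc
        t = Xr @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        p_a = (Xr.T @ t) / tt
        q_a = float(yr @ t) / tt
        Xr = Xr - np.outer(t, p_a)
        yr = yr - q_a * t
        W.append(w)
        P.append(p_a)
        Q.append(q_a)
        tvar.append(tt / max(n - 1, 1))
        # fold scalings/deflations back into a raw-coordinate direction:
        # v_a = prod_{j<a} (I - w_j p_j^T) D_{j+1}^{-1} w_a
        v = w.copy()
        for j in range(a - 1, -1, -1):
            sj = scales[j + 1]
            if sj is not None:
                v = v / sj
            v = v - W[j] * float(P[j] @ v)
        B[a + 1] = B[a] + q_a * v
        achieved = a + 1

    loadings = np.array(P) if P else np.zeros((0, p))
    return _Path(x_mean, y_mean, B[: achieved + 1], loadings,
                 np.array(tvar), achieved)


def _pcr_path(X: np.ndarray, y: np.ndarray, max_k: int) -> _Path:
    X, y = _check_xy(X, y, max_k)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size else 0
    achieved = min(max_k, rank)
    B = np.zeros((achieved + 1, p))
    for a in range(achieved):
        # score regression coefficient for PC a: (u_a . yc) / s_a
        beta = float(U[:, a] @ yc) / S[a]
        B[a + 1] = B[a] + beta * Vt[a]
    return _Path(x_mean, y_mean, B, Vt[:achieved].copy(),
                 (S[:achieved] ** 2) / max(n - 1, 1), achieved)


def coefficient_path(X: np.ndarray, y: np.ndarray, max_k: int, method: str) -> _Path:
    """Coefficient path for any engine; used by cross-validation."""
    if method == "PLS":
        return _pls_path(X, y, max_k, modified=False)
    if method == "MPLS":
        return _pls_path(X, y, max_k, modified=True)
    if method == "PCR":
        return _pcr_path(X, y, max_k)
    raise DataValidationError(f"unknown method {method!r}; expected one of {METHODS}")


def _fit(
    X, y, k, method, *,
    constituent=None, treatment=None, wavelengths=None, msc_reference=None,
) -> CalibrationModel:
    path = coefficient_path(X, y, k, method)
    if path.achieved < k:
        raise DegenerateDataError(
            f"{method}: requested {k} factors but data support only "
            f"{path.achieved} (rank limit)"
        )
    X = np.asarray(X, dtype=float)
    wl = (np.asarray(wavelengths, dtype=float) if wavelengths is not None
          else np.arange(X.shape[1], dtype=float))
    fitted = path.predict(X, k)
    y = np.asarray(y, dtype=float).ravel()
    return CalibrationModel(
        method=method,
        constituent=constituent,
        treatment=treatment,
        n_factors=k,
        wavelengths=wl,
        x_mean=path.x_mean,
        y_mean=path.y_mean,
        coefficients=path.B[k],
        loadings=path.loadings[:k] if path.loadings.size else path.loadings,
        scores_variance=path.scores_variance[:k],
        msc_reference=msc_reference,
        training_stats={
            "n": int(X.shape[0]),
            "sse": float(np.sum((fitted - y) ** 2)),
        },
    )


def fit_pls(X, y, k, **kw) -> CalibrationModel:
    """Standard NIPALS PLS with k factors."""
    return _fit(X, y, k, "PLS", **kw)


def fit_mpls(X, y, k, **kw) -> CalibrationModel:
    """Modified PLS (per-factor residual standardization) with k factors.

    Identical to :func:`fit_pls` for k = 1, since no standardization is
    applied before the first factor.
    """
    return _fit(X, y, k, "MPLS", **kw)


def fit_pcr(X, y, k, **kw) -> CalibrationModel:
    """Principal component regression on the first k PC scores."""
    return _fit(X, y, k, "PCR", **kw)


def predict(model: CalibrationModel, X: np.ndarray) -> np.ndarray:
    """Predict constituent values for processed spectra on the model grid."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.coefficients.size:
        raise DataValidationError(
            f"spectra have {X.shape[1]} points but the model grid has "
            f"{model.coefficients.size}"
        )
    out = model.y_mean + (X - model.x_mean) @ model.coefficients
    return out[0] if single else out


def extract_loadings(model: CalibrationModel, component_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm loading vector for one factor, with its wavelengths.

    The sign convention makes the largest-magnitude element positive so
    serialized loadings are reproducible.
    """
    if model.loadings is None or not (0 <= component_index < len(model.loadings)):
        raise DataValidationError(
            f"component index {component_index} out of range "
            f"(model has {model.n_factors} factors)"
        )
    v = model.loadings[component_index].astype(float)
    nrm = np.linalg.norm(v)
    if nrm < 1e-300:
        raise DegenerateDataError("zero loading vector")
    v = v / nrm
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return model.wavelengths, v
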