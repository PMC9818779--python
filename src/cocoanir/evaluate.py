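"""Model evaluation: k-fold cross-validation, outlier culling, SEC/SECV/
R2/RPD metrics and interpretation bands, forward interval-PLS wavelength
selection, and the scatter x derivative treatment grid search.

Conventions (documented once, used everywhere):

* SEC uses calibration degrees of freedom ``N - 1 - n_factors``; SECV uses
  ``N - 1``.
* R2 is ``1 - SSE/SST`` (not a squared correlation), clamped to [0, 1].
* RPD is the reference SD of the evaluated set divided by SECV.
* Outliers are samples whose cross-validated residual exceeds 2.5 residual
  SDs; at most two elimination passes are run, then the model is refit and
  re-cross-validated on the retained set.
* The default CV fold seed is 20221220; folds are a seeded permutation
  split into parts whose sizes differ by at most one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import SpectralDataset
from .exceptions import DataValidationError, DegenerateDataError
from .preprocess import MathTreatment, apply_treatment_matrix, standard_treatment_grid
from .regress import coefficient_path, max_factors

DEFAULT_CV_SEED = 20221220
OUTLIER_THRESHOLD = 2.5
MAX_OUTLIER_PASSES = 2


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def kfold_indices(n: int, k_folds: int, seed: int = DEFAULT_CV_SEED) -> list[np.ndarray]:
    """Deterministic seeded k-fold partition; fold sizes differ by <= 1."""
    if n < k_folds:
        raise DataValidationError(f"need at least {k_folds} samples, have {n}")
    if k_folds < 2:
        raise DataValidationError("k_folds must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k_folds)]


def cv_path(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "PLS",
    max_k: int | None = None,
    k_folds: int = 5,
    seed: int = DEFAULT_CV_SEED,
) -> np.ndarray:
    """Out-of-fold predictions for every factor count 0..max_k.

    Returns an ``(n, max_k+1)`` matrix: column k holds each sample's
    prediction from the k-factor model of the fold that excluded it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    folds = kfold_indices(n, k_folds, seed)
    if max_k is None:
        min_train = n - max(len(f) for f in folds)
        max_k = max_factors(min_train, X.shape[1])
    preds = np.empty((n, max_k + 1))
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        path = coefficient_path(X[train], y[train], max_k, method)
        for k in range(max_k + 1):
            preds[fold, k] = path.predict(X[fold], k)
    return preds


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "PLS",
    n_factors: int = 1,
    k_folds: int = 5,
    seed: int = DEFAULT_CV_SEED,
) -> np.ndarray:
    """Per-sample out-of-fold predictions at a fixed factor count."""
    return cv_path(X, y, method, n_factors, k_folds, seed)[:, n_factors]


def rpd(sd: float, secv: float) -> float:
    """Ratio of performance to deviation: reference SD over SECV."""
    if secv <= 0:
        raise DegenerateDataError("SECV must be > 0 for RPD")
    return sd / secv


def rmsecv(y_ref: np.ndarray, y_cv: np.ndarray) -> float:
    """Root-mean-square error of cross-validation."""
    y_ref = np.asarray(y_ref, float)
    y_cv = np.asarray(y_cv, float)
    return float(np.sqrt(np.mean((y_cv - y_ref) ** 2)))


def select_n_factors(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "MPLS",
    max_k: int | None = None,
    k_folds: int = 5,
    seed: int = DEFAULT_CV_SEED,
    parsimony: float = 1.02,
) -> int:
    """Cross-validated factor selection with a parsimony rule.

    Picks the smallest k whose SECV is within ``parsimony`` (default 2%)
    of the minimum SECV over 0..max_k; ties break toward smaller k, and
    the chosen k never exceeds the argmin.
    """
    y = np.asarray(y, dtype=float).ravel()
    preds = cv_path(X, y, method, max_k, k_folds, seed)
    secv = np.sqrt(np.sum((preds - y[:, None]) ** 2, axis=0) / max(y.size - 1, 1))
    best = int(np.argmin(secv))
    for k in range(best + 1):
        if secv[k] <= parsimony * secv[best]:
            return k
    return best


# ---------------------------------------------------------------------------
# metrics and interpretation
# ---------------------------------------------------------------------------

def compute_metrics(
    y_ref: np.ndarray,
    y_fit: np.ndarray,
    y_cv: np.ndarray,
    n_factors: int = 0,
) -> dict:
    """SEC, R2cal, SECV, R2cv and RPD for one calibration.

    ``y_fit`` are fitted (calibration) values, ``y_cv`` out-of-fold
    predictions; all three vectors are aligned with the retained samples.
    """
    y_ref = np.asarray(y_ref, float).ravel()
    y_fit = np.asarray(y_fit, float).ravel()
    y_cv = np.asarray(y_cv, float).ravel()
    n = y_ref.size
    if not (y_fit.size == n and y_cv.size == n) or n < 3:
        raise DataValidationError("metric vectors must be equal length >= 3")
    sd = float(y_ref.std(ddof=1))
    sst = float(np.sum((y_ref - y_ref.mean()) ** 2))
    if sst < 1e-300:
        raise DegenerateDataError("reference values are constant; R2 undefined")
    sse_cal = float(np.sum((y_fit - y_ref) ** 2))
    sse_cv = float(np.sum((y_cv - y_ref) ** 2))
    sec = np.sqrt(sse_cal / max(n - 1 - n_factors, 1))
    secv = np.sqrt(sse_cv / (n - 1))
    r2cal = min(max(1.0 - sse_cal / sst, 0.0), 1.0)
    r2cv = min(max(1.0 - sse_cv / sst, 0.0), 1.0)
    perfect = secv < 1e-12
    rpd = sd / max(secv, 1e-12)
    return {
        "n": n,
        "mean": float(y_ref.mean()),
        "sd": sd,
        "sec": float(sec),
        "r2cal": r2cal,
        "secv": float(secv),
        "r2cv": r2cv,
        "rpd": float(rpd),
        "rpd_is_guarded": perfect,
    }


def interpret(r2cv: float, rpd: float) -> tuple[str, str]:
    """Quality bands for a cross-validated model.

    R2cv: >= 0.91 excellent, >= 0.82 good, >= 0.66 approximate, else poor
    (values in the conventionally unstated gaps 0.81-0.82 and 0.90-0.91
    resolve to the lower band). RPD: > 2.5 adequate, < 1.5 unsatisfactory,
    otherwise intermediate.
    """
    if r2cv >= 0.91:
        r2_label = "excellent"
    elif r2cv >= 0.82:
        r2_label = "good"
    elif r2cv >= 0.66:
        r2_label = "approximate"
    else:
        r2_label = "poor"
    if rpd > 2.5:
        rpd_label = "adequate"
    elif rpd < 1.5:
        rpd_label = "unsatisfactory"
    else:
        rpd_label = "intermediate"
    return r2_label, rpd_label


def remove_outliers(
    y_ref: np.ndarray,
    y_pred: np.ndarray,
    threshold: float = OUTLIER_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """T-statistic outlier rule on prediction residuals.

    ``T_i = |y_pred_i - y_ref_i| / SD(residuals)``; samples with
    T > threshold are flagged. Returns ``(retained_idx, removed_idx)``.
    """
    y_ref = np.asarray(y_ref, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    res = y_pred - y_ref
    sd = res.std(ddof=1)
    if sd < 1e-300:
        return np.arange(y_ref.size), np.array([], dtype=int)
    t = np.abs(res) / sd
    removed = np.nonzero(t > threshold)[0]
    retained = np.nonzero(t <= threshold)[0]
    if retained.size == 0:
        raise DegenerateDataError("outlier rule flagged every sample")
    return retained, removed


# ---------------------------------------------------------------------------
# full single-constituent evaluation (cull -> refit -> metrics)
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """One table row of calibration statistics for one constituent/treatment."""

    constituent: str
    method: str
    treatment: MathTreatment | None
    n: int
    mean: float
    sd: float
    sec: float
    r2cal: float
    secv: float
    r2cv: float
    rpd: float
    n_factors: int
    removed_ids: list[str] = field(default_factory=list)
    r2_label: str = ""
    rpd_label: str = ""

    def to_row(self) -> dict:
        return {
            "scatter": self.treatment.scatter if self.treatment else "NONE",
            "math_treatment": self.treatment.code if self.treatment else "0,0,1,1",
            "constituent": self.constituent,
            "method": self.method,
            "N": self.n,
            "mean": round(self.mean, 4),
            "SD": round(self.sd, 4),
            "SEcal": round(self.sec, 4),
            "R2cal": round(self.r2cal, 4),
            "SEcv": round(self.secv, 4),
            "R2cv": round(self.r2cv, 4),
            "RPD": round(self.rpd, 4),
            "n_factors": self.n_factors,
            "removed": ";".join(self.removed_ids),
            "interpretation": self.r2_label,
            "rpd_flag": self.rpd_label,
        }


def evaluate_constituent(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: list[str] | None = None,
    method: str = "MPLS",
    constituent: str = "",
    treatment: MathTreatment | None = None,
    k_folds: int = 5,
    seed: int = DEFAULT_CV_SEED,
    outlier_threshold: float = OUTLIER_THRESHOLD,
    max_passes: int = MAX_OUTLIER_PASSES,
    max_k: int | None = None,
) -> EvaluationReport:
    """Cull outliers (<= ``max_passes`` cross-validated passes), refit, and
    report calibration/cross-validation statistics on the retained set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if sample_ids is None:
        sample_ids = [str(i) for i in range(y.size)]
    retained = np.arange(y.size)
    removed_ids: list[str] = []

    for _ in range(max_passes):
        k = select_n_factors(X[retained], y[retained], method, max_k, k_folds, seed)
        y_cv = kfold_cv(X[retained], y[retained], method, k, k_folds, seed)
        keep, drop = remove_outliers(y[retained], y_cv, outlier_threshold)
        if drop.size == 0:
            break
        removed_ids.extend(sample_ids[i] for i in retained[drop])
        retained = retained[keep]

    Xr, yr = X[retained], y[retained]
    k = select_n_factors(Xr, yr, method, max_k, k_folds, seed)
    path = coefficient_path(Xr, yr, max(k, 1), method)
    y_fit = path.predict(Xr, k)
    y_cv = kfold_cv(Xr, yr, method, k, k_folds, seed)
    m = compute_metrics(yr, y_fit, y_cv, n_factors=k)
    r2_label, rpd_label = interpret(m["r2cv"], m["rpd"])
    return EvaluationReport(
        constituent=constituent, method=method, treatment=treatment,
        n=m["n"], mean=m["mean"], sd=m["sd"], sec=m["sec"], r2cal=m["r2cal"],
        secv=m["secv"], r2cv=m["r2cv"], rpd=m["rpd"], n_factors=k,
        removed_ids=removed_ids, r2_label=r2_label, rpd_label=rpd_label,
    )


# ---------------------------------------------------------------------------
# treatment grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    best: EvaluationReport
    reports: list[EvaluationReport]


def grid_search(
    ds: SpectralDataset,
    constituent: str,
    treatments: list[MathTreatment] | None = None,
    method: str = "MPLS",
    k_folds: int = 5,
    seed: int = DEFAULT_CV_SEED,
    max_k: int | None = None,
) -> GridSearchResult:
    """Run the full pipeline per treatment cell and pick the SECV winner.

    Each cell: apply the treatment (MSC reference = calibration-set mean,
    frozen), cross-validate with factor selection, cull outliers, refit,
    compute metrics. Samples lacking a laboratory value for the
    constituent are excluded up front.
    """
    if treatments is None:
        treatments = standard_treatment_grid()
    y_all, present = ds.constituent(constituent)
    if present.sum() < k_folds + 2:
        raise DegenerateDataError(
            f"too few reference values for {constituent!r} ({int(present.sum())})"
        )
    idx = np.nonzero(present)[0]
    X0 = ds.absorbance[idx]
    y = y_all[idx]
    ids = [ds.sample_ids[i] for i in idx]
    reports = []
    for t in treatments:
        Xp, _, _ = apply_treatment_matrix(X0, ds.wavelengths, t)
        reports.append(
            evaluate_constituent(
                Xp, y, ids, method=method, constituent=constituent,
                treatment=t, k_folds=k_folds, seed=seed, max_k=max_k,
            )
        )
    best = min(reports, key=lambda r: r.secv)
    return GridSearchResult(best, reports)


# ---------------------------------------------------------------------------
# forward interval PLS
# ---------------------------------------------------------------------------

@dataclass
class IPLSResult:
    """Forward interval-selection trace.

    ``interval_bounds`` are (lo_nm, hi_nm) pairs; ``selected_intervals``
    is the greedy selection order; ``rmsecv_path`` gives the running
    RMSECV after each accepted interval.
    """

    interval_bounds: list[tuple[float, float]]
    per_interval_rmsecv: list[float]
    selected_intervals: list[int]
    rmsecv_path: list[float]
    final_rmsecv: float
    n_factors_final: int


def interval_slices(n_points: int, n_intervals: int) -> list[slice]:
    """Contiguous equal-size intervals; remainder points go to the last."""
    if n_intervals > n_points:
        raise DataValidationError(
            f"{n_intervals} intervals exceed the {n_points}-point grid"
        )
    base = n_points // n_intervals
    starts = [i * base for i in range(n_intervals)]
    ends = starts[1:] + [n_points]
    return [slice(s, e) for s, e in zip(starts, ends)]


def ipls_forward(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray | None = None,
    n_intervals: int = 30,
    method: str = "PLS",
    k_folds: int = 5,
    seed: int = DEFAULT_CV_SEED,
    steps: str | int = "auto",
    max_k: int | None = None,
) -> IPLSResult:
    """Forward interval-PLS wavelength selection.

    Step 1 fits one cross-validated model per interval and selects the
    RMSECV-minimizing interval. With ``steps="auto"`` the forward mode
    continues greedily, adding the interval that most reduces RMSECV and
    stopping when no addition improves it; ``steps=1`` stops after the
    first interval.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    wl = (np.asarray(wavelengths, dtype=float) if wavelengths is not None
          else np.arange(X.shape[1], dtype=float))
    slices = interval_slices(X.shape[1], n_intervals)
    bounds = [(float(wl[s][0]), float(wl[s][-1])) for s in slices]

    def best_rmsecv(cols: np.ndarray) -> tuple[float, int]:
        Xs = X[:, cols]
        cap = max_k if max_k is not None else max_factors(
            y.size - y.size // k_folds, Xs.shape[1]
        )
        k = select_n_factors(Xs, y, method, cap, k_folds, seed)
        return rmsecv(y, kfold_cv(Xs, y, method, k, k_folds, seed)), k

    per_interval = []
    for s in slices:
        r, _ = best_rmsecv(np.arange(s.start, s.stop))
        per_interval.append(r)
    first = int(np.argmin(per_interval))
    selected = [first]
    current_cols = np.arange(slices[first].start, slices[first].stop)
    best, k_final = best_rmsecv(current_cols)
    path = [best]

    if steps == "auto":
        while len(selected) < n_intervals:
            cand_best, cand_idx, cand_k = None, None, None
            for j in range(n_intervals):
                if j in selected:
                    continue
                cols = np.sort(np.concatenate(
                    [current_cols, np.arange(slices[j].start, slices[j].stop)]
                ))
                r, k = best_rmsecv(cols)
                if cand_best is None or r < cand_best:
                    cand_best, cand_idx, cand_k = r, j, k
            if cand_best is None or cand_best >= best * (1 - 1e-9):
                break
            selected.append(cand_idx)
            current_cols = np.sort(np.concatenate(
                [current_cols,
                 np.arange(slices[cand_idx].start, slices[cand_idx].stop)]
            ))
            best, k_final = cand_best, cand_k
            path.append(best)
    return IPLSResult(
        interval_bounds=bounds,
        per_interval_rmsecv=per_interval,
        selected_intervals=selected,
        rmsecv_path=path,
        final_rmsecv=best,
        n_factors_final=k_final,
    )
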