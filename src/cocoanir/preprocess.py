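"""Spectral pre-treatments: scatter corrections and derivative codes.

Reflectance spectra of particulate samples carry multiplicative and
additive scatter that is unrelated to composition. Two standard families
of corrections are provided:

* **SNV_DT** — standard normal variate (per-spectrum centering/scaling to
  unit SD) followed by detrending (removal of the least-squares quadratic
  baseline in wavelength, Barnes-style).
* **MSC** — multiplicative scatter correction: each spectrum is regressed
  on a reference spectrum (by default the calibration-set mean) and the
  fitted affine transform is inverted.

Derivatives and smoothing follow the WinISI-style 4-digit code
``d,g,s1,s2``: *d* is the derivative order (0-2), *g* the gap in data
points of the central difference, *s1*/*s2* the widths of two successive
running-mean smoothings (width 1 = no smoothing). The stencil is a central
gap difference with edge truncation: output points whose stencil is
incomplete are dropped and the retained wavelength sub-grid is reported.

Processing order is fixed: scatter correction first, then the derivative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import SpectralDataset
from .exceptions import ConfigError, DataValidationError, DegenerateDataError

SCATTER_MODES = ("NONE", "SNV_DT", "MSC")


@dataclass(frozen=True)
class MathTreatment:
    """A scatter-correction choice plus a derivative/smoothing code.

    Rendered in the conventional form ``scatter`` + ``"d,g,s1,s2"``,
    e.g. ``SNV_DT 1,4,4,1``.
    """

    scatter: str = "NONE"
    d: int = 0
    g: int = 0
    s1: int = 1
    s2: int = 1

    def __post_init__(self) -> None:
        if self.scatter not in SCATTER_MODES:
            raise ConfigError(
                f"scatter must be one of {SCATTER_MODES}, got {self.scatter!r}"
            )
        if self.d not in (0, 1, 2):
            raise ConfigError(f"derivative order d must be 0, 1 or 2, got {self.d}")
        if self.g < 0:
            raise ConfigError(f"gap g must be >= 0, got {self.g}")
        if self.d > 0 and self.g < 1:
            raise ConfigError("derivative order > 0 requires gap g >= 1")
        if self.s1 < 1 or self.s2 < 1:
            raise ConfigError("smoothing widths s1, s2 must be >= 1")

    @property
    def code(self) -> str:
        return f"{self.d},{self.g},{self.s1},{self.s2}"

    @classmethod
    def from_code(cls, scatter: str, code: str) -> "MathTreatment":
        """Parse ``"1,4,4,1"`` (or the compact ``"1441"``) into a treatment."""
        code = code.strip()
        if "," in code:
            parts = [int(p) for p in code.split(",")]
        elif len(code) == 4 and code.isdigit():
            parts = [int(c) for c in code]
        else:
            raise ConfigError(f"cannot parse math-treatment code {code!r}")
        if len(parts) != 4:
            raise ConfigError(f"math-treatment code needs 4 digits, got {code!r}")
        return cls(scatter, *parts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.scatter} {self.code}"


#: the nine-cell treatment grid conventionally screened for these models
STANDARD_SCATTERS = SCATTER_MODES
STANDARD_CODES = ("0,0,1,1", "1,4,4,1", "2,5,5,1")


def standard_treatment_grid() -> list[MathTreatment]:
    """All 9 combinations of the standard scatter modes and codes."""
    return [
        MathTreatment.from_code(s, c)
        for s in STANDARD_SCATTERS
        for c in STANDARD_CODES
    ]


# ---------------------------------------------------------------------------
# elementary corrections (single spectrum)
# ---------------------------------------------------------------------------

def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and scale to unit sample SD (n-1).

    Affine-invariant: ``snv(a*x + b) == snv(x)`` for a > 0.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise DataValidationError("SNV needs at least 2 points")
    sd = x.std(ddof=1)
    if sd < 1e-15:
        raise DegenerateDataError("constant spectrum cannot be SNV-normalized")
    return (x - x.mean()) / sd


def detrend(spectrum: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """Remove the least-squares 2nd-degree polynomial baseline in wavelength.

    The residual is orthogonal to {1, lambda, lambda^2}; applying detrend
    twice changes nothing.
    """
    x = np.asarray(spectrum, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    if x.size < 3:
        raise DataValidationError("detrend needs at least 3 points")
    if wl.size != x.size:
        raise DataValidationError("wavelengths and spectrum lengths differ")
    # scale wavelengths to [-1, 1] for numerical conditioning
    w = (wl - wl.mean()) / max(np.ptp(wl) / 2, 1e-12)
    coeffs = np.polynomial.polynomial.polyfit(w, x, 2)
    return x - np.polynomial.polynomial.polyval(w, coeffs)


def snv_detrend(spectrum: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """SNV followed by detrending (the SNV_DT scatter correction).

    The detrended spectrum is re-standardized to unit sample SD so the
    correction is idempotent: a second application is a no-op.
    """
    z = detrend(snv(spectrum), wavelengths)
    sd = z.std(ddof=1)
    if sd < 1e-15:
        raise DegenerateDataError("spectrum is a pure quadratic baseline")
    return z / sd


def msc(spectrum: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Fits ``spectrum = a + b * reference`` by least squares and returns
    ``(spectrum - a) / b``, removing per-sample affine scatter exactly.
    """
    x = np.asarray(spectrum, dtype=float)
    r = np.asarray(reference, dtype=float)
    if x.size != r.size:
        raise DataValidationError("spectrum and MSC reference are on different grids")
    if r.std(ddof=0) < 1e-15:
        raise DegenerateDataError("MSC reference has zero variance")
    rc = r - r.mean()
    b = (x @ rc) / (rc @ rc)
    if abs(b) < 1e-12:
        raise DegenerateDataError("fitted MSC slope is zero; cannot invert")
    a = x.mean() - b * r.mean()
    return (x - a) / b


# ---------------------------------------------------------------------------
# gap-segment derivative
# ---------------------------------------------------------------------------

def gap_derivative(
    spectrum: np.ndarray, d: int, g: int, s1: int, s2: int
) -> tuple[np.ndarray, int]:
    """Apply a ``d,g,s1,s2`` derivative code to one spectrum.

    The central gap difference ``x[i+g] - x[i-g]`` is applied *d* times,
    then two centered running means of widths *s1* and *s2*. Edges with
    incomplete stencils are truncated.

    Returns
    -------
    (values, offset)
        ``values[j]`` is registered at original grid index ``j + offset``.
        For even smoothing widths the window is ``[i - s/2, i + s/2 - 1]``.
    """
    y = np.asarray(spectrum, dtype=float).copy()
    if y.ndim != 1:
        raise DataValidationError("gap_derivative expects a 1-D spectrum")
    offset = 0
    for _ in range(d):
        if y.size <= 2 * g:
            raise DataValidationError(
                f"spectrum too short ({y.size} pts) for gap {g} derivative"
            )
        y = y[2 * g:] - y[:-2 * g]
        offset += g
    for s in (s1, s2):
        if s == 1:
            continue
        if y.size < s:
            raise DataValidationError(
                f"spectrum too short ({y.size} pts) for smoothing width {s}"
            )
        y = np.convolve(y, np.full(s, 1.0 / s), mode="valid")
        offset += s // 2
    if y.size < 1:
        raise DataValidationError("treatment leaves no retained points")
    return y, offset


def _derivative_matrix(X: np.ndarray, t: MathTreatment) -> tuple[np.ndarray, int, int]:
    """Row-wise derivative code; returns (matrix, offset, retained length)."""
    first, offset = gap_derivative(X[0], t.d, t.g, t.s1, t.s2)
    out = np.empty((X.shape[0], first.size))
    out[0] = first
    for i in range(1, X.shape[0]):
        out[i], _ = gap_derivative(X[i], t.d, t.g, t.s1, t.s2)
    return out, offset, first.size


# ---------------------------------------------------------------------------
# full treatment pipeline
# ---------------------------------------------------------------------------

def apply_treatment_matrix(
    X: np.ndarray,
    wavelengths: np.ndarray,
    treatment: MathTreatment,
    msc_reference: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Apply scatter correction then derivative to a spectra matrix.

    For MSC, the reference defaults to the mean of the *given* spectra (the
    calibration set) and is returned so it can be frozen in a fitted model
    and reused for later predictions.

    Returns ``(processed, retained_wavelengths, msc_reference_used)``.
    """
    X = np.asarray(X, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    used_ref = None
    if treatment.scatter == "SNV_DT":
        X = np.stack([snv_detrend(row, wl) for row in X])
    elif treatment.scatter == "MSC":
        used_ref = (
            X.mean(axis=0) if msc_reference is None
            else np.asarray(msc_reference, dtype=float)
        )
        X = np.stack([msc(row, used_ref) for row in X])
    if treatment.d == 0 and treatment.s1 == 1 and treatment.s2 == 1:
        return X, wl, used_ref
    Xd, offset, m = _derivative_matrix(X, treatment)
    return Xd, wl[offset:offset + m], used_ref


def apply_treatment(
    ds: SpectralDataset,
    treatment: MathTreatment,
    msc_reference: np.ndarray | None = None,
) -> tuple[SpectralDataset, np.ndarray | None]:
    """Dataset-level :func:`apply_treatment_matrix`.

    Returns the processed dataset (on its retained grid) and the MSC
    reference actually used (None unless the treatment uses MSC).
    """
    Xp, wl, ref = apply_treatment_matrix(
        ds.absorbance, ds.wavelengths, treatment, msc_reference
    )
    out = SpectralDataset(
        wl, Xp, list(ds.sample_ids),
        ds.references.copy() if ds.references is not None else None,
        None, ds.preparation,
    )
    return out, ref
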