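"""Spectral dataset model and I/O.

A :class:`SpectralDataset` couples an absorbance matrix (samples x
wavelengths, log(1/R)) with its wavelength grid, sample identifiers, an
optional table of laboratory reference values, the instrument profile the
spectra were acquired on, and the sample preparation (whole beans or
de-husked ground powder).

Two instrument profiles used throughout the package are provided as module
constants: a benchtop scanning monochromator covering 850-2500 nm at 0.5 nm
(:data:`BENCHTOP`) and a portable spectrometer covering 900-1680 nm at 2 nm
(:data:`PORTABLE`).

CSV layout
----------
Spectra:    ``sample_id,850.0,850.5,...`` one row per sample.
References: ``sample_id,fat,protein,tpc,ph,ta,fi,dm,ash,shell`` (any subset
of constituent columns; empty cells mark missing values).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataValidationError, GridError, ModelIOError

#: absolute tolerance (nm) when matching wavelengths against a grid
GRID_TOL = 1e-6

MODEL_SCHEMA_VERSION = 1

PREPARATIONS = ("whole", "ground")

#: constituents carried in reference tables, in canonical column order
CONSTITUENTS = ("fat", "protein", "tpc", "ph", "ta", "fi", "dm", "ash", "shell")


@dataclass(frozen=True)
class InstrumentProfile:
    """An instrument's wavelength sampling: ``[lambda_min, lambda_max]`` nm
    at a fixed step. The range must contain an integer number of steps."""

    name: str
    lambda_min: float
    lambda_max: float
    step: float

    def __post_init__(self) -> None:
        if not self.lambda_min < self.lambda_max:
            raise GridError(
                f"{self.name}: lambda_min ({self.lambda_min}) must be < "
                f"lambda_max ({self.lambda_max})"
            )
        if self.step <= 0:
            raise GridError(f"{self.name}: step must be > 0, got {self.step}")
        n = (self.lambda_max - self.lambda_min) / self.step
        if abs(n - round(n)) > 1e-9:
            raise GridError(
                f"{self.name}: ({self.lambda_max} - {self.lambda_min}) / "
                f"{self.step} is not an integer number of steps"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.lambda_max - self.lambda_min) / self.step)) + 1

    def grid(self) -> np.ndarray:
        """The full wavelength grid in nm."""
        return np.linspace(self.lambda_min, self.lambda_max, self.n_points)


BENCHTOP = InstrumentProfile("benchtop", 850.0, 2500.0, 0.5)
PORTABLE = InstrumentProfile("portable", 900.0, 1680.0, 2.0)

PROFILES = {"benchtop": BENCHTOP, "portable": PORTABLE}


@dataclass
class SpectralDataset:
    """Absorbance spectra plus linked reference values.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm.
    absorbance
        Matrix of shape ``(n_samples, n_wavelengths)``; no missing cells.
    sample_ids
        Unique labels, one per row.
    references
        Optional DataFrame indexed like ``sample_ids`` with one column per
        constituent; NaN marks a missing laboratory value (the sample is
        then excluded only from that constituent's calibration).
    instrument
        Profile the spectra are registered on (None for ad-hoc grids).
    preparation
        ``"whole"`` or ``"ground"``.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    references: pd.DataFrame | None = None
    instrument: InstrumentProfile | None = None
    preparation: str = "ground"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavelengths.ndim != 1:
            raise DataValidationError("wavelengths must be 1-D")
        if self.absorbance.ndim != 2:
            raise DataValidationError("absorbance must be 2-D (samples x wavelengths)")
        if self.absorbance.shape != (len(self.sample_ids), self.wavelengths.size):
            raise DataValidationError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavelengths.size} wavelengths"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise DataValidationError("wavelengths must be strictly increasing")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            raise DataValidationError(f"duplicate sample_ids: {sorted(dupes)}")
        if not np.all(np.isfinite(self.absorbance)):
            raise DataValidationError("absorbance matrix contains missing/non-finite cells")
        if self.preparation not in PREPARATIONS:
            raise DataValidationError(
                f"preparation must be one of {PREPARATIONS}, got {self.preparation!r}"
            )
        if self.references is not None:
            self.references = self.references.reindex(self.sample_ids)
            if len(self.references) != len(self.sample_ids):
                raise DataValidationError("references index does not cover sample_ids")

    # -- basic properties -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavelengths(self) -> int:
        return int(self.wavelengths.size)

    def constituent(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(values, present_mask)`` for one constituent.

        ``present_mask`` flags samples with a laboratory value; values are
        aligned with ``sample_ids``.
        """
        if self.references is None or name not in self.references.columns:
            raise DataValidationError(f"no reference values for constituent {name!r}")
        vals = self.references[name].to_numpy(dtype=float)
        return vals, np.isfinite(vals)

    def subset(self, index: Sequence[int]) -> "SpectralDataset":
        """Row subset by positional index (order preserved)."""
        idx = np.asarray(index, dtype=int)
        ids = [self.sample_ids[i] for i in idx]
        refs = self.references.iloc[idx] if self.references is not None else None
        return SpectralDataset(
            self.wavelengths.copy(), self.absorbance[idx], ids, refs,
            self.instrument, self.preparation,
        )


# ---------------------------------------------------------------------------
# replicate averaging / range restriction
# ---------------------------------------------------------------------------

def average_replicates(scans: Iterable[np.ndarray]) -> np.ndarray:
    """Point-wise arithmetic mean of repeated acquisitions of one sample.

    Acquisition protocols average a few consecutive scans (three in the
    workflows this package targets) into the stored spectrum.
    """
    arrs = [np.asarray(s, dtype=float) for s in scans]
    if not arrs:
        raise DataValidationError("average_replicates needs at least one scan")
    n = arrs[0].size
    for a in arrs:
        if a.ndim != 1 or a.size != n:
            raise GridError("scans are not on identical grids")
    return np.mean(arrs, axis=0)


def restrict_range(
    ds: SpectralDataset, lo: float, hi: float, step: float | None = None
) -> SpectralDataset:
    """Restrict a dataset to ``[lo, hi]`` nm, optionally decimating to a
    coarser step by exact column selection (never interpolation).

    The requested grid must be a subset of the source grid; the decimation
    step must be an integer multiple of the source step.
    """
    wl = ds.wavelengths
    src_step = float(np.min(np.diff(wl)))
    if step is None:
        step = src_step
    ratio = step / src_step
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise GridError(
            f"requested step {step} nm is not an integer multiple of the "
            f"source step {src_step} nm"
        )
    ratio = int(round(ratio))
    start_candidates = np.nonzero(np.abs(wl - lo) <= GRID_TOL)[0]
    if start_candidates.size == 0:
        raise GridError(f"requested start {lo} nm is not on the source grid")
    start = int(start_candidates[0])
    if hi < lo or hi - wl[-1] > GRID_TOL:
        raise GridError(f"requested range {lo}-{hi} nm exceeds the source grid")
    idx = np.arange(start, wl.size, ratio)
    idx = idx[wl[idx] <= hi + GRID_TOL]
    new_wl = wl[idx]
    # decimation must land exactly on the requested step
    if new_wl.size > 1 and np.any(np.abs(np.diff(new_wl) - step) > 1e-6):
        raise GridError("source grid is not uniform over the requested range")
    instrument = None
    if new_wl.size > 1:
        instrument = InstrumentProfile(
            (ds.instrument.name if ds.instrument else "custom") + "_restricted",
            float(new_wl[0]), float(new_wl[-1]), float(step),
        )
    refs = ds.references.copy() if ds.references is not None else None
    return SpectralDataset(
        new_wl, ds.absorbance[:, idx].copy(), list(ds.sample_ids), refs,
        instrument, ds.preparation,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_spectra(
    path: str | Path,
    instrument: InstrumentProfile,
    *,
    reflectance: bool = False,
    preparation: str = "ground",
) -> SpectralDataset:
    """Load a spectra CSV and validate its header against an instrument grid.

    The header row is ``sample_id`` followed by wavelengths in nm; the
    wavelengths must match the instrument grid within ``GRID_TOL``. With
    ``reflectance=True`` values are converted to absorbance as log10(1/R)
    at ingest.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise DataValidationError(
            f"first column must be 'sample_id', got {df.columns[0]!r}"
        )
    try:
        wl = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise GridError(f"non-numeric wavelength column in header: {exc}") from exc
    grid = instrument.grid()
    if wl.size != grid.size or np.any(np.abs(wl - grid) > GRID_TOL):
        if wl.size == grid.size:
            bad = int(np.argmax(np.abs(wl - grid) > GRID_TOL))
            raise GridError(
                f"wavelength {wl[bad]} nm at column {bad} is off the "
                f"{instrument.name} grid (expected {grid[bad]} nm)"
            )
        off = wl[~np.isin(np.round(wl / instrument.step), np.round(grid / instrument.step))]
        first = off[0] if off.size else wl[0]
        raise GridError(
            f"{wl.size} columns do not match the {instrument.name} grid of "
            f"{grid.size} points (first offending wavelength: {first} nm)"
        )
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if reflectance:
        if np.any(values <= 0):
            raise DataValidationError("reflectance values must be > 0 to convert")
        values = np.log10(1.0 / values)
    return SpectralDataset(
        grid, values, df["sample_id"].astype(str).tolist(),
        instrument=instrument, preparation=preparation,
    )


def save_spectra(ds: SpectralDataset, path: str | Path) -> None:
    """Write a dataset's spectra to CSV (lossless to well below 1e-12)."""
    df = pd.DataFrame(ds.absorbance, columns=[f"{w:.10g}" for w in ds.wavelengths])
    df.insert(0, "sample_id", ds.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def load_references(path: str | Path) -> pd.DataFrame:
    """Load a reference-value CSV (``sample_id`` + constituent columns)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise DataValidationError("reference CSV must have a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise DataValidationError("duplicate sample_id in reference CSV")
    return df.set_index("sample_id")


def save_references(refs: pd.DataFrame, path: str | Path) -> None:
    refs.to_csv(path, index_label="sample_id", float_format="%.17g")


def attach_references(ds: SpectralDataset, refs: pd.DataFrame) -> SpectralDataset:
    """Return a copy of *ds* with reference values linked by sample id."""
    return SpectralDataset(
        ds.wavelengths.copy(), ds.absorbance.copy(), list(ds.sample_ids),
        refs, ds.instrument, ds.preparation,
    )


# ---------------------------------------------------------------------------
# model (de)serialization -- JSON round trip for CalibrationModel
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Serialize a fitted :class:`~cocoanir.regress.CalibrationModel` to JSON."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "method": model.method,
        "constituent": model.constituent,
        "treatment": {
            "scatter": model.treatment.scatter,
            "code": model.treatment.code,
        } if model.treatment is not None else None,
        "n_factors": int(model.n_factors),
        "wavelength_grid": model.wavelengths.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": float(model.y_mean),
        "coefficients": model.coefficients.tolist(),
        "loadings": model.loadings.tolist() if model.loadings is not None else None,
        "scores_variance": (
            model.scores_variance.tolist() if model.scores_variance is not None else None
        ),
        "msc_reference": (
            model.msc_reference.tolist() if model.msc_reference is not None else None
        ),
        "training_stats": model.training_stats,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`.

    The round trip preserves predictions bitwise to within serialization
    precision (<= 1e-12).
    """
    from .preprocess import MathTreatment
    from .regress import CalibrationModel

    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise ModelIOError(f"cannot parse model file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelIOError(
            f"model schema version {version!r} is not supported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    t = payload.get("treatment")
    treatment = (
        MathTreatment.from_code(t["scatter"], t["code"]) if t is not None else None
    )
    return CalibrationModel(
        method=payload["method"],
        constituent=payload["constituent"],
        treatment=treatment,
        n_factors=payload["n_factors"],
        wavelengths=np.array(payload["wavelength_grid"], dtype=float),
        x_mean=np.array(payload["x_mean"], dtype=float),
        y_mean=payload["y_mean"],
        coefficients=np.array(payload["coefficients"], dtype=float),
        loadings=(
            np.array(payload["loadings"], dtype=float)
            if payload.get("loadings") is not None else None
        ),
        scores_variance=(
            np.array(payload["scores_variance"], dtype=float)
            if payload.get("scores_variance") is not None else None
        ),
        msc_reference=(
            np.array(payload["msc_reference"], dtype=float)
            if payload.get("msc_reference") is not None else None
        ),
        training_stats=payload.get("training_stats"),
    )
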