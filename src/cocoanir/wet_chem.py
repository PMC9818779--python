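"""Arithmetic of the wet-chemistry reference assays.

Only the calculations are implemented — the oven, furnace, Soxhlet,
Kjeldahl and titration procedures themselves produce the raw numbers these
functions consume.

Covered assays: gravimetric dry matter / moisture, shell fraction,
Kjeldahl protein (N x 6.25), Folin-Ciocalteu total phenolic content with a
gallic-acid standard line, fermentation index (A460/A530 of an acidified
methanol extract), titratable acidity (NaOH titration to pH 8.1), and
descriptive statistics (min/max/mean/SD/CV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataValidationError, DegenerateDataError

#: Kjeldahl nitrogen-to-protein conversion factor
PROTEIN_FACTOR = 6.25

#: gallic-acid standard concentrations (mg/L) for the Folin-Ciocalteu curve
GALLIC_STANDARDS_MG_L = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0)

# Folin-Ciocalteu assay geometry: 0.05 g defatted powder extracted into
# 10 mL; 0.1 mL extract + 3 mL water + 0.5 mL reagent + 1 mL Na2CO3 = 4.6 mL
FOLIN_EXTRACT_ML = 10.0
FOLIN_ALIQUOT_ML = 0.1
FOLIN_ASSAY_ML = 4.6
FOLIN_MASS_G = 0.05

# titration defaults: 25 mL aliquot of a 5 g / 100 mL extract, 0.05 M NaOH
TA_MOLARITY = 0.05
TA_ALIQUOT_ML = 25.0
TA_EXTRACT_ML = 100.0
TA_POWDER_G = 5.0

ACETIC_ACID_G_PER_MOL = 60.05


def fermentation_index(a460: float, a530: float) -> tuple[float, str]:
    """FI = A460/A530; > 1 classifies the beans as well-fermented.

    The ratio tracks the loss of anthocyanin color as fermentation
    proceeds; exactly 1 falls on the under-fermented side (strict >).
    """
    if a460 < 0 or a530 < 0:
        raise DataValidationError("absorbances must be >= 0")
    if a530 == 0:
        raise DegenerateDataError("A530 is zero; FI undefined")
    fi = a460 / a530
    return fi, ("well-fermented" if fi > 1 else "under-fermented")


def protein_from_nitrogen(nitrogen_pct: float) -> float:
    """Crude protein %: total Kjeldahl nitrogen % times 6.25."""
    if nitrogen_pct < 0:
        raise DataValidationError("nitrogen must be >= 0")
    return PROTEIN_FACTOR * nitrogen_pct


@dataclass(frozen=True)
class CalibrationLine:
    """OLS standard line: absorbance = intercept + slope * conc (mg/L)."""

    slope: float
    intercept: float
    r2: float

    def concentration(self, absorbance: float) -> float:
        return (absorbance - self.intercept) / self.slope


def fit_gallic_line(
    concentrations_mg_l: np.ndarray | tuple = GALLIC_STANDARDS_MG_L,
    absorbances: np.ndarray | None = None,
) -> CalibrationLine:
    """Fit the gallic-acid standard curve by ordinary least squares."""
    c = np.asarray(concentrations_mg_l, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size != a.size or c.size < 2:
        raise DataValidationError("need >= 2 paired standards")
    slope, intercept = np.polyfit(c, a, 1)
    fitted = intercept + slope * c
    sst = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - float(np.sum((a - fitted) ** 2)) / sst if sst > 0 else 1.0
    if abs(slope) < 1e-15:
        raise DegenerateDataError("standard line has zero slope")
    return CalibrationLine(float(slope), float(intercept), float(r2))


def tpc_from_absorbance(
    a765: float,
    line: CalibrationLine,
    extract_volume_ml: float = FOLIN_EXTRACT_ML,
    aliquot_ml: float = FOLIN_ALIQUOT_ML,
    assay_volume_ml: float = FOLIN_ASSAY_ML,
    mass_g: float = FOLIN_MASS_G,
) -> float:
    """Total phenolic content in mg gallic-acid equivalents per g defatted
    mass.

    The assay concentration from the standard line is scaled by the assay
    dilution (assay volume / extract aliquot) and the extract volume, then
    divided by the extracted mass.
    """
    if min(extract_volume_ml, aliquot_ml, assay_volume_ml, mass_g) <= 0:
        raise DataValidationError("volumes and mass must be > 0")
    conc_mg_l = line.concentration(a765)
    if conc_mg_l < -1e-9:
        raise DataValidationError(
            f"A765 = {a765} is below the standard-line intercept; "
            "negative concentration"
        )
    dilution = assay_volume_ml / aliquot_ml
    return max(conc_mg_l, 0.0) * dilution * (extract_volume_ml / 1000.0) / mass_g


def tpc_percent(tpc_mg_per_g: float) -> float:
    """mg GAE per g defatted mass expressed as a mass percentage."""
    return tpc_mg_per_g / 10.0


def titratable_acidity(
    v_naoh_ml: float,
    molarity: float = TA_MOLARITY,
    aliquot_ml: float = TA_ALIQUOT_ML,
    extract_ml: float = TA_EXTRACT_ML,
    powder_g: float = TA_POWDER_G,
) -> float:
    """Titratable acidity in mmol NaOH per 100 g powder.

    ``TA = M * V * (extract/aliquot) * (100/powder)``; at the default
    geometry this reduces to 4 * V.
    """
    if min(molarity, aliquot_ml, extract_ml, powder_g) <= 0 or v_naoh_ml < 0:
        raise DataValidationError("titration quantities must be positive")
    return molarity * v_naoh_ml * (extract_ml / aliquot_ml) * (100.0 / powder_g)


def ta_as_acetic_pct(ta_mmol_per_100g: float) -> float:
    """Secondary unit: % acetic acid (w/w), 1:1 stoichiometry."""
    return ta_mmol_per_100g * ACETIC_ACID_G_PER_MOL / 1000.0


def dry_matter(wet_g: float, dry_g: float) -> tuple[float, float]:
    """Gravimetric dry matter: returns ``(DM %, moisture %)``.

    DM and moisture always sum to exactly 100.
    """
    if wet_g <= 0 or dry_g <= 0:
        raise DataValidationError("weights must be > 0")
    if dry_g > wet_g:
        raise DataValidationError("dry weight exceeds wet weight")
    moisture = 100.0 * (wet_g - dry_g) / wet_g
    return 100.0 - moisture, moisture


def shell_fraction(peel_g: float, nib_g: float) -> float:
    """Shell percentage of the whole bean: 100 * peel / (peel + nib)."""
    if peel_g < 0 or nib_g < 0:
        raise DataValidationError("weights must be >= 0")
    total = peel_g + nib_g
    if total == 0:
        raise DegenerateDataError("zero total weight")
    return 100.0 * peel_g / total


@dataclass(frozen=True)
class DescriptiveStats:
    minimum: float
    maximum: float
    mean: float
    sd: float
    cv_pct: float


def descriptive_stats(values: np.ndarray) -> DescriptiveStats:
    """Min, max, mean, sample SD (n-1) and CV% = 100 * SD / mean."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise DataValidationError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if mean == 0:
        raise DegenerateDataError("mean is zero; CV undefined")
    return DescriptiveStats(float(v.min()), float(v.max()), mean, sd,
                            100.0 * sd / mean)


def stats_table(references) -> "pd.DataFrame":
    """Descriptive-statistics table (one row per constituent column)."""
    import pandas as pd

    rows = {}
    for col in references.columns:
        s = descriptive_stats(references[col].to_numpy())
        rows[col] = {
            "Minimum": s.minimum, "Maximum": s.maximum, "Mean": s.mean,
            "SD": s.sd, "CV (%)": s.cv_pct,
        }
    return pd.DataFrame(rows).T
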