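"""Seeded generator of cocoa-like constituent tables and NIR spectra.

The generator is the package's ground-truth harness: it draws a
constituent table from a truncated, correlated normal parameterized by
typical commercial cocoa-bean statistics, then renders absorbance spectra
as linear Beer-Lambert mixtures of Gaussian component bands on a smooth
baseline.

Two preparation modes are produced:

* ``ground`` — clean de-husked powder spectra: linear mixture + small
  i.i.d. noise.
* ``whole`` — degraded whole-bean spectra: per-sample multiplicative and
  additive scatter, a wavelength slope, a broadband shell-interference
  component proportional to each sample's shell fraction (uncorrelated
  with the other constituents), and stronger noise. This emulates the
  shell reflecting incident light before it interacts with the nib.

Band centers follow standard NIR assignments (lipid C-H overtones near
1210/1725/1744/2320 nm, water O-H at 1450/1930 nm, protein N-H at
1500/2057/2130 nm, carboxylic-acid combination bands near 940/1106/1395
nm, phenolics near 1420 nm). Traits without a direct absorber of their
own (pH, ash) receive weak effective proxy bands standing in for the
indirect spectral associations NIR calibrations actually exploit; band
widths and intensities are tunable configuration, not claims about true
cocoa extinction coefficients.

Every stochastic draw derives from a named, counter-independent stream of
the single global seed, so adding a constituent never perturbs the draws
of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset_io import (
    BENCHTOP, PORTABLE, InstrumentProfile, SpectralDataset,
)
from .exceptions import ConfigError

DEFAULT_SEED = 20221220
DEFAULT_N_SAMPLES = 56


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center/width in nm, peak intensity in
    absorbance units per unit concentration of its component."""

    center: float
    width: float
    intensity: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError("band width must be > 0")
        if self.intensity < 0:
            raise ConfigError("band intensity must be >= 0")

    def profile(self, wl: np.ndarray) -> np.ndarray:
        return self.intensity * np.exp(-0.5 * ((wl - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class ComponentDist:
    """Truncated-normal marginal for one constituent (native units)."""

    mean: float
    sd: float
    minimum: float
    maximum: float


#: typical commercial cocoa-bean composition statistics (native units):
#: fat/protein/dm/ash/shell in %, tpc in mg GAE/g defatted, ta in
#: mmol NaOH/100 g, fi dimensionless, ph in pH units
DEFAULT_COMPOSITIONS: dict[str, ComponentDist] = {
    "shell": ComponentDist(13.25, 1.54, 11.13, 18.34),
    "fat": ComponentDist(44.72, 1.94, 36.96, 48.39),
    "protein": ComponentDist(13.85, 1.13, 8.32, 15.43),
    "tpc": ComponentDist(56.42, 13.32, 32.58, 98.04),
    "ph": ComponentDist(5.58, 0.36, 4.84, 6.47),
    "ta": ComponentDist(17.19, 4.22, 8.20, 26.81),
    "fi": ComponentDist(1.29, 0.49, 0.57, 2.24),
    "dm": ComponentDist(94.51, 0.59, 93.30, 95.76),
    "ash": ComponentDist(2.99, 0.30, 2.34, 3.66),
}

#: default pairwise correlations; fat vs non-fat solids (where phenolics
#: concentrate) is negative, acidity and pH move oppositely
DEFAULT_CORRELATIONS: tuple[tuple[str, str, float], ...] = (
    ("fat", "tpc", -0.3),
    ("ta", "ph", -0.6),
)

# spectral drivers: constituent -> bands. "water" is driven by moisture
# (100 - dm); "carb" is the non-fat-solids remainder, giving the broad
# carbohydrate background its natural anti-correlation with fat.
DEFAULT_BANDS: dict[str, tuple[BandSpec, ...]] = {
    "fat": (
        BandSpec(1210, 30, 0.004), BandSpec(1725, 18, 0.005),
        BandSpec(1744, 16, 0.005), BandSpec(2320, 22, 0.004),
    ),
    "water": (BandSpec(1450, 45, 0.020), BandSpec(1930, 55, 0.030)),
    "protein": (
        BandSpec(1500, 30, 0.006), BandSpec(2057, 25, 0.006),
        BandSpec(2130, 28, 0.006),
    ),
    "carb": (BandSpec(2100, 40, 0.002), BandSpec(1580, 60, 0.001)),
    "tpc": (BandSpec(1420, 35, 0.00025),),
    "fi": (BandSpec(1435, 30, 0.006),),
    "ta": (
        BandSpec(940, 25, 0.0008), BandSpec(1106, 20, 0.0006),
        BandSpec(1395, 28, 0.0010),
    ),
    "ph": (BandSpec(910, 20, 0.008),),
    "ash": (BandSpec(1390, 30, 0.008), BandSpec(2180, 40, 0.006)),
}

#: broadband shell interference: smooth, spans the whole window
SHELL_BAND = BandSpec(1500, 350, 1.0)


@dataclass
class SyntheticSpec:
    """Full generator configuration; the defaults are the study conditions
    every pipeline test runs under."""

    composition_dist: dict[str, ComponentDist] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITIONS))
    correlations: tuple[tuple[str, str, float], ...] = DEFAULT_CORRELATIONS
    bands: dict[str, tuple[BandSpec, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    n_samples: int = DEFAULT_N_SAMPLES
    seed: int = DEFAULT_SEED
    noise_sd: float = 0.002            # AU, ground mode
    whole_noise_sd: float = 0.006      # AU, whole-bean mode
    scatter_mult_sd: float = 0.15      # multiplicative scatter, whole mode
    scatter_add_sd: float = 0.05       # additive offset, whole mode
    scatter_slope_sd: float = 0.02     # wavelength slope, whole mode
    shell_interference: float = 0.010  # AU per shell %, whole mode


def _stream(seed: int, *names: str) -> np.random.Generator:
    """Named, order-independent RNG stream derived from the global seed."""
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng([seed & 0x7FFFFFFF, *keys])


def _correlation_matrix(names: list[str],
                        pairs: tuple[tuple[str, str, float], ...]) -> np.ndarray:
    corr = np.eye(len(names))
    pos = {n: i for i, n in enumerate(names)}
    for a, b, rho in pairs:
        if a in pos and b in pos:
            corr[pos[a], pos[b]] = corr[pos[b], pos[a]] = rho
    # guard positive definiteness of user-supplied correlations
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ConfigError("constituent correlation matrix is not positive definite")
    return corr


def generate_compositions(spec: SyntheticSpec | None = None) -> pd.DataFrame:
    """Draw a constituent table from the truncated correlated normal.

    Each constituent's raw standard normals come from its own named
    stream; the Cholesky mixing uses a fixed constituent ordering so the
    draws are stable under configuration growth. Values are truncated to
    the stated [min, max] bounds.
    """
    spec = spec or SyntheticSpec()
    names = list(spec.composition_dist.keys())
    n = spec.n_samples
    Z = np.column_stack([
        _stream(spec.seed, "comp", name).standard_normal(n) for name in names
    ])
    L = np.linalg.cholesky(_correlation_matrix(names, spec.correlations))
    Zc = Z @ L.T
    data = {}
    for j, name in enumerate(names):
        d = spec.composition_dist[name]
        data[name] = np.clip(d.mean + d.sd * Zc[:, j], d.minimum, d.maximum)
    ids = [f"S{i + 1:02d}" for i in range(n)]
    return pd.DataFrame(data, index=pd.Index(ids, name="sample_id"))


def _driver_concentrations(comps: pd.DataFrame) -> dict[str, np.ndarray]:
    """Map band-library drivers to per-sample concentrations."""
    conc: dict[str, np.ndarray] = {}
    for name in ("fat", "protein", "tpc", "fi", "ta", "ph", "ash"):
        if name in comps.columns:
            conc[name] = comps[name].to_numpy(dtype=float)
    if "dm" in comps.columns:
        conc["water"] = 100.0 - comps["dm"].to_numpy(dtype=float)
    n = len(comps)
    total = np.zeros(n)
    for k in ("fat", "protein", "ash", "water"):
        total += conc.get(k, np.zeros(n))
    conc["carb"] = 100.0 - total  # non-fat-solids remainder
    return conc


def _baseline(wl: np.ndarray) -> np.ndarray:
    # gentle increasing baseline typical of log(1/R) spectra
    return 0.30 + 8e-5 * (wl - 850.0)


def generate_spectra(
    compositions: pd.DataFrame,
    spec: SyntheticSpec | None = None,
    mode: str = "ground",
    instrument: InstrumentProfile = BENCHTOP,
) -> SpectralDataset:
    """Render Beer-Lambert mixture spectra for a constituent table.

    Ground mode is exactly linear in the driver concentrations up to the
    additive noise; whole mode adds per-sample affine scatter, a
    wavelength slope and the shell-interference component before noise.
    """
    if mode not in ("ground", "whole"):
        raise ConfigError(f"mode must be 'ground' or 'whole', got {mode!r}")
    spec = spec or SyntheticSpec()
    wl = instrument.grid()
    n = len(compositions)
    conc = _driver_concentrations(compositions)

    A = np.tile(_baseline(wl), (n, 1))
    for driver, bands in spec.bands.items():
        if driver not in conc:
            continue
        shape = np.sum([b.profile(wl) for b in bands], axis=0)
        A += np.outer(conc[driver], shape)

    if mode == "whole":
        rng = _stream(spec.seed, "scatter", instrument.name)
        a = 1.0 + spec.scatter_mult_sd * rng.standard_normal(n)
        b = spec.scatter_add_sd * rng.standard_normal(n)
        slope = spec.scatter_slope_sd * rng.standard_normal(n)
        ramp = (wl - wl.mean()) / max(np.ptp(wl), 1.0)
        A = a[:, None] * A + b[:, None] + np.outer(slope, ramp)
        if "shell" in compositions.columns:
            shell = compositions["shell"].to_numpy(dtype=float)
            A += spec.shell_interference * np.outer(shell, SHELL_BAND.profile(wl))
        noise_sd = spec.whole_noise_sd
    else:
        noise_sd = spec.noise_sd

    if noise_sd > 0:
        rng_n = _stream(spec.seed, "noise", instrument.name, mode)
        A = A + noise_sd * rng_n.standard_normal(A.shape)

    return SpectralDataset(
        wl, A, list(compositions.index.astype(str)),
        references=compositions.copy(), instrument=instrument,
        preparation=mode,
    )


@dataclass
class Fixture:
    """A complete simulated study: one constituent table and spectra for
    both instruments in both preparation modes."""

    compositions: pd.DataFrame
    datasets: dict[tuple[str, str], SpectralDataset]
    spec: SyntheticSpec

    def get(self, instrument: str, mode: str) -> SpectralDataset:
        return self.datasets[(instrument, mode)]


def make_fixture(
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = DEFAULT_SEED,
    spec: SyntheticSpec | None = None,
) -> Fixture:
    """Deterministic bundled dataset: 56 samples by default, both
    instrument grids (3301 and 391 points), both preparation modes."""
    spec = spec or SyntheticSpec()
    spec = replace(spec, n_samples=n_samples, seed=seed)
    comps = generate_compositions(spec)
    datasets = {}
    for instrument in (BENCHTOP, PORTABLE):
        for mode in ("ground", "whole"):
            datasets[(instrument.name, mode)] = generate_spectra(
                comps, spec, mode, instrument
            )
    return Fixture(comps, datasets, spec)
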