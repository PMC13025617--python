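"""Radiocarbon calibration against mixed marine/terrestrial curves.

Bone collagen of people with partly marine diets carries a mixture of
atmospheric and surface-ocean carbon, so a measurement must be calibrated
against a blend of a terrestrial curve (IntCal-style) and a marine curve
(Marine-style) shifted by the local reservoir offset ΔR.  Mixing is done in
the 14C-age domain: mu_mix = (1-p) mu_T + p mu_M with the diet-fraction
uncertainty sigma_p entering through the curve-separation term
sigma_p^2 (mu_M - mu_T)^2 — a first-order match to OxCal's Mix_Curve.

calBP is defined as calendar years before 1950 CE.  Real IntCal20/Marine20
files are user-supplied in the standard .14c column format; the test suite
and demo use toy curves from :mod:`admixchron.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HPD_LEVEL = 0.954  # the conventional "95.4%" two-sigma region


@dataclass
class CalibrationCurve:
    """14C-age mean and 1-sigma as a function of calendar age (calBP)."""

    cal_grid: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.cal_grid = np.asarray(self.cal_grid, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.cal_grid.size == self.mu.size == self.sigma.size):
            raise ValueError("curve arrays differ in length")
        if (np.diff(self.cal_grid) <= 0).any():
            raise ValueError("cal grid must be strictly increasing")
        if (self.sigma <= 0).any():
            raise ValueError("curve sigma must be positive")


@dataclass
class ReservoirSpec:
    """Local marine reservoir offset ΔR (14C years)."""

    delta_R_mean: float = -140.0
    delta_R_sd: float = 35.0

    def __post_init__(self) -> None:
        if self.delta_R_sd < 0:
            raise ValueError("ΔR sd must be non-negative")


@dataclass
class DietSpec:
    """Fraction of marine carbon in dietary protein."""

    marine_fraction_mean: float = 0.5
    marine_fraction_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.marine_fraction_mean <= 1.0:
            raise ValueError("marine fraction must be in [0, 1]")
        if self.marine_fraction_sd < 0:
            raise ValueError("marine fraction sd must be non-negative")


@dataclass
class CalibratedDate:
    """Posterior over calendar age for one measurement."""

    cal_grid: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)
    mean: float
    sd: float
    hpd_95: list[tuple[float, float]]

    @property
    def envelope(self) -> tuple[float, float]:
        """(oldest, youngest) bound across all HPD intervals, paper style."""
        old = max(hi for _, hi in self.hpd_95)
        young = min(lo for lo, _ in self.hpd_95)
        return old, young


# ----------------------------------------------------------------------
# curve I/O and arithmetic
# ----------------------------------------------------------------------

def read_curve_14c(path: str | Path, step: float = 5.0) -> CalibrationCurve:
    """Read a .14c three-column file (calBP, 14C age, 1-sigma).

    Lines starting with ``#`` are skipped; comma or whitespace separated.
    The curve is linearly interpolated onto a uniform ``step``-year grid.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            rows.append(tuple(float(v) for v in parts[:3]))
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least 2 data rows")
    arr = np.array(rows)
    cal, mu, sig = arr[:, 0], arr[:, 1], arr[:, 2]
    order = np.argsort(cal)
    if np.unique(cal).size != cal.size:
        raise ValueError(f"{path}: duplicate calBP values")
    # the file may run old-to-young; re-sorting must preserve the pairing
    cal, mu, sig = cal[order], mu[order], sig[order]
    grid = np.arange(cal[0], cal[-1] + step / 2, step)
    return CalibrationCurve(
        grid, np.interp(grid, cal, mu), np.interp(grid, cal, sig),
        name=Path(path).stem,
    )


def apply_reservoir(curve: CalibrationCurve, rs: ReservoirSpec) -> CalibrationCurve:
    """Shift the curve by ΔR and fold the ΔR uncertainty into sigma."""
    return CalibrationCurve(
        curve.cal_grid.copy(),
        curve.mu + rs.delta_R_mean,
        np.sqrt(curve.sigma**2 + rs.delta_R_sd**2),
        name=f"{curve.name}+dR({rs.delta_R_mean:+g})",
    )


def mix_curves(
    terrestrial: CalibrationCurve,
    marine: CalibrationCurve,
    diet: DietSpec,
) -> CalibrationCurve:
    """Diet-weighted blend of a terrestrial and a (reservoir-corrected) marine curve."""
    if terrestrial.cal_grid.shape != marine.cal_grid.shape or not np.allclose(
        terrestrial.cal_grid, marine.cal_grid
    ):
        raise ValueError("curves are not on a common cal grid")
    p = diet.marine_fraction_mean
    sp = diet.marine_fraction_sd
    mu = (1.0 - p) * terrestrial.mu + p * marine.mu
    sigma = np.sqrt(
        (1.0 - p) ** 2 * terrestrial.sigma**2
        + p**2 * marine.sigma**2
        + sp**2 * (marine.mu - terrestrial.mu) ** 2
    )
    return CalibrationCurve(
        terrestrial.cal_grid.copy(), mu, sigma, name=f"mix(p={p:g})"
    )


# ----------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------

def calibrate(
    age_14c: float, sigma_m: float, curve: CalibrationCurve
) -> CalibratedDate:
    """Calibrate a 14C measurement under a flat calendar prior.

    posterior(cal) ∝ Normal(age_14c; mu(cal), sqrt(sigma_m^2 + sigma(cal)^2)),
    normalised over the curve grid; the 95.4% region is the highest-density
    set of grid points (possibly several disjoint intervals).
    """
    if sigma_m <= 0:
        raise ValueError("measurement sigma must be positive")
    s2 = sigma_m**2 + curve.sigma**2
    loglik = -0.5 * (age_14c - curve.mu) ** 2 / s2 - 0.5 * np.log(s2)
    dens = np.exp(loglik - loglik.max())
    total = dens.sum()
    # detectability guard on the un-shifted scale
    if np.exp(loglik.max()) * total < 1e-12:
        raise ValueError("measurement off curve: posterior mass vanishes")
    dens /= total
    mean = float((curve.cal_grid * dens).sum())
    sd = float(np.sqrt(((curve.cal_grid - mean) ** 2 * dens).sum()))
    hpd = _hpd_intervals(curve.cal_grid, dens, HPD_LEVEL)
    return CalibratedDate(curve.cal_grid, dens, mean, sd, hpd)


def _hpd_intervals(
    grid: np.ndarray, dens: np.ndarray, level: float
) -> list[tuple[float, float]]:
    order = np.argsort(dens)[::-1]
    cum = np.cumsum(dens[order])
    k = int(np.searchsorted(cum, level)) + 1
    member = np.zeros(dens.size, dtype=bool)
    member[order[:k]] = True
    intervals = []
    i = 0
    while i < member.size:
        if member[i]:
            j = i
            while j + 1 < member.size and member[j + 1]:
                j += 1
            intervals.append((float(grid[i]), float(grid[j])))
            i = j + 1
        else:
            i += 1
    return intervals


def hpd_mass(date: CalibratedDate) -> float:
    """Posterior mass actually contained in the reported HPD intervals."""
    mass = 0.0
    for lo, hi in date.hpd_95:
        sel = (date.cal_grid >= lo) & (date.cal_grid <= hi)
        mass += float(date.density[sel].sum())
    return mass


# ----------------------------------------------------------------------
# sensitivity grid
# ----------------------------------------------------------------------

def _as_reservoir(spec) -> ReservoirSpec:
    return spec if isinstance(spec, ReservoirSpec) else ReservoirSpec(*spec)


def _as_diet(spec) -> DietSpec:
    if isinstance(spec, DietSpec):
        return spec
    if np.isscalar(spec):
        return DietSpec(float(spec), 0.0)
    return DietSpec(*spec)


def sensitivity_grid(
    measurement: tuple[float, float],
    terrestrial: CalibrationCurve,
    marine: CalibrationCurve,
    delta_R_list,
    marine_fraction_list,
) -> pd.DataFrame:
    """Calibrate one measurement over a (ΔR, marine-fraction) grid.

    Returns one row per cell with posterior mean/sd, the HPD envelope, and
    the full :class:`CalibratedDate` in the ``date`` column.
    """
    if not len(delta_R_list) or not len(marine_fraction_list):
        raise ValueError("sensitivity lists must be non-empty")
    age, sig = measurement
    rows = []
    for dr in delta_R_list:
        rs = _as_reservoir(dr)
        marine_rs = apply_reservoir(marine, rs)
        for mf in marine_fraction_list:
            diet = _as_diet(mf)
            mixed = mix_curves(terrestrial, marine_rs, diet)
            date = calibrate(age, sig, mixed)
            old, young = date.envelope
            rows.append(
                {
                    "delta_R": rs.delta_R_mean,
                    "delta_R_sd": rs.delta_R_sd,
                    "marine_fraction": diet.marine_fraction_mean,
                    "marine_fraction_sd": diet.marine_fraction_sd,
                    "mean": date.mean,
                    "sd": date.sd,
                    "hpd_old": old,
                    "hpd_young": young,
                    "date": date,
                }
            )
    return pd.DataFrame(rows)
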