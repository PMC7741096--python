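"""Radiocarbon calibration: determinations -> calendar-probability densities.

Given a determination (CRA +/- error) and a calibration curve, the calendar
density at cal BP year t is proportional to the curve-error-aware normal
density

    p(t)  ~  exp( -(CRA - mu(t))^2 / (2 (err^2 + s(t)^2)) ) / sqrt(err^2 + s(t)^2)

normalized to unit mass over its support (truncated where the cumulative tail
mass falls below 1e-6 per side).  No prior reweighting or bomb-peak handling;
cal BP means years before 1950 CE.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import CalCurve, ReservoirOffset, mix_curves

__all__ = [
    "C14Date",
    "CalDensity",
    "calibrate_date",
    "median_cal",
    "read_dates",
    "index_dates",
    "cal_medians",
    "density_rows",
]

TAIL_MASS = 1e-6

SITE_TYPES = ("open_air", "closed")
CONTEXT_FLAGS = ("secure", "insecure")


@dataclass
class C14Date:
    """One radiocarbon determination with its archaeological metadata."""

    lab_id: str
    cra: float
    error: float
    site_id: str = ""
    site_type: str = "closed"
    lon: float = float("nan")
    lat: float = float("nan")
    fraction_marine: float = 0.0
    offset: ReservoirOffset = field(default_factory=ReservoirOffset)
    context_flag: str = "secure"

    def __post_init__(self) -> None:
        if self.error <= 0:
            raise ValueError(f"{self.lab_id}: error must be > 0")
        if self.cra <= 0:
            raise ValueError(f"{self.lab_id}: cra must be > 0")
        if not 0.0 <= self.fraction_marine <= 1.0:
            raise ValueError(f"{self.lab_id}: fraction_marine must lie in [0, 1]")
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"{self.lab_id}: unknown site_type {self.site_type!r}")
        if self.context_flag not in CONTEXT_FLAGS:
            raise ValueError(f"{self.lab_id}: unknown context_flag {self.context_flag!r}")

    @property
    def mixture_key(self) -> tuple:
        """Key identifying which effective curve calibrates this date."""
        return (self.fraction_marine, self.offset.delta_r, self.offset.delta_r_sigma)


@dataclass
class CalDensity:
    """Normalized probability mass over a uniform cal BP grid."""

    grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.grid.shape != self.mass.shape or self.grid.ndim != 1:
            raise ValueError("grid and mass must be 1-d arrays of equal length")
        if np.any(self.mass < 0):
            raise ValueError("mass must be >= 0")
        total = float(self.mass.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass must sum to 1 (got {total!r})")
        if self.grid.size > 1:
            steps = np.diff(self.grid)
            if not (np.all(steps > 0) and np.allclose(steps, steps[0])):
                raise ValueError("grid must be uniform ascending")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size > 1 else 1.0


def _effective_curve(date: C14Date, atm: CalCurve, mar: CalCurve | None) -> CalCurve:
    if date.fraction_marine == 0.0:
        return atm
    if mar is None:
        raise ValueError(f"{date.lab_id}: marine curve required (fraction_marine > 0)")
    return mix_curves(atm, mar, date.fraction_marine, date.offset)


def calibrate_date(date: C14Date, atm: CalCurve, mar: CalCurve | None = None) -> CalDensity:
    """Calibrate one determination against the (possibly mixed) curve."""
    curve = _effective_curve(date, atm, mar)
    var = date.error**2 + curve.sigma**2
    sd = np.sqrt(var)
    if date.cra > float(np.max(curve.mu + 10 * sd)) or date.cra < float(
        np.min(curve.mu - 10 * sd)
    ):
        raise ValueError(
            f"{date.lab_id}: CRA {date.cra:g} lies outside curve '{curve.label}'"
        )
    z = (date.cra - curve.mu) / sd
    dens = np.exp(-0.5 * z**2) / sd
    total = float(dens.sum())
    if total <= 0 or not np.isfinite(total):
        raise ValueError(f"{date.lab_id}: calibrated density has zero mass")
    mass = dens / total
    cum = np.cumsum(mass)
    lo = int(np.searchsorted(cum, TAIL_MASS))
    hi = int(np.searchsorted(cum, 1.0 - TAIL_MASS)) + 1
    lo = max(lo, 0)
    hi = min(hi, mass.size)
    grid = curve.grid[lo:hi]
    mass = mass[lo:hi]
    return CalDensity(grid=grid, mass=mass / mass.sum())


def median_cal(d: CalDensity) -> float:
    """Median calendar age: accumulate mass from the older end until 0.5."""
    order = np.argsort(d.grid)[::-1]
    cum = np.cumsum(d.mass[order])
    i = int(np.searchsorted(cum, 0.5))
    i = min(i, order.size - 1)
    return float(d.grid[order[i]])


# ---------------------------------------------------------------------------
# vectorized internals shared by the SPD / KDE / null-model pipeline


def _mass_matrix(cras: np.ndarray, errs: np.ndarray, curve: CalCurve, grid: np.ndarray) -> np.ndarray:
    """Per-cell calibrated mass for many dates sharing one curve, on `grid`.

    Each row is normalized to unit mass over the grid (no tail truncation);
    callers must supply a grid that covers the plausible calendar range.
    """
    mu = curve.mu_at(grid)
    sig = curve.sigma_at(grid)
    var = np.asarray(errs, float)[:, None] ** 2 + sig[None, :] ** 2
    z2 = (np.asarray(cras, float)[:, None] - mu[None, :]) ** 2 / var
    dens = np.exp(-0.5 * z2) / np.sqrt(var)
    totals = dens.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("a date calibrates to zero mass on the supplied grid")
    return dens / totals


def density_rows(dates: list[C14Date], atm: CalCurve, mar: CalCurve | None, grid: np.ndarray) -> np.ndarray:
    """Stack of per-date calibrated mass rows on a shared grid.

    Dates are grouped by their curve mixture (marine fraction, DeltaR) so each
    effective curve is built once.
    """
    grid = np.asarray(grid, dtype=float)
    out = np.empty((len(dates), grid.size), dtype=float)
    groups: dict[tuple, list[int]] = {}
    for i, d in enumerate(dates):
        groups.setdefault(d.mixture_key, []).append(i)
    for key, idx in groups.items():
        curve = _effective_curve(dates[idx[0]], atm, mar)
        cras = np.array([dates[i].cra for i in idx], float)
        errs = np.array([dates[i].error for i in idx], float)
        out[idx, :] = _mass_matrix(cras, errs, curve, grid)
    return out


def cal_medians(
    dates: list[C14Date],
    atm: CalCurve,
    mar: CalCurve | None = None,
    grid: np.ndarray | None = None,
) -> dict[str, float]:
    """Median calibrated age per lab_id, computed on a shared grid."""
    if not dates:
        return {}
    if grid is None:
        grid = atm.grid
    rows = density_rows(dates, atm, mar, grid)
    # accumulate from the older (high cal BP) end
    rev = rows[:, ::-1]
    cum = np.cumsum(rev, axis=1)
    idx = np.argmax(cum >= 0.5, axis=1)
    grid_rev = np.asarray(grid, float)[::-1]
    return {d.lab_id: float(grid_rev[i]) for d, i in zip(dates, idx)}


# ---------------------------------------------------------------------------
# I/O

_DATE_COLUMNS = {"lab_id", "cra", "error"}


def read_dates(path) -> list[C14Date]:
    """Read a radiocarbon date table (CSV) into C14Date records.

    Required columns: lab_id, cra, error.  Optional: site_id, site_type,
    lon, lat, fraction_marine, delta_r, delta_r_sigma, context_flag; missing
    optional fields take their typed defaults.
    """
    df = pd.read_csv(path)
    missing = _DATE_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    def get(row, col, default):
        if col in df.columns and not pd.isna(row[col]):
            return row[col]
        return default

    dates = []
    for _, row in df.iterrows():
        offset = ReservoirOffset(
            delta_r=float(get(row, "delta_r", 0.0)),
            delta_r_sigma=float(get(row, "delta_r_sigma", 0.0)),
        )
        dates.append(
            C14Date(
                lab_id=str(row["lab_id"]),
                cra=float(row["cra"]),
                error=float(row["error"]),
                site_id=str(get(row, "site_id", "")),
                site_type=str(get(row, "site_type", "closed")),
                lon=float(get(row, "lon", float("nan"))),
                lat=float(get(row, "lat", float("nan"))),
                fraction_marine=float(get(row, "fraction_marine", 0.0)),
                offset=offset,
                context_flag=str(get(row, "context_flag", "secure")),
            )
        )
    return dates


def index_dates(dates: list[C14Date]) -> dict[str, C14Date]:
    """Map lab_id -> C14Date; duplicate lab ids are an error."""
    out: dict[str, C14Date] = {}
    for d in dates:
        if d.lab_id in out:
            raise ValueError(f"duplicate lab_id {d.lab_id!r}")
        out[d.lab_id] = d
    return out
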