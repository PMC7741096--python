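"""Calibration curves: loading, resampling, and marine/atmospheric mixing.

A calibration curve maps calendar age (cal BP, years before 1950 CE) to the
expected conventional radiocarbon age mu(t) with a 1-sigma curve error s(t).
Curves are held on a uniform 1-year grid so that calibrated densities are exact
per-cell mass vectors and numerical differentiation downstream is stable.

Human bone samples with partially marine diets are calibrated against a
per-sample mixture of the atmospheric and marine curves, weighted by the
marine-diet fraction F, with a local reservoir offset DeltaR (applied to the
marine component only, since DeltaR is defined relative to the marine curve).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CalCurve", "ReservoirOffset", "load_curve", "mix_curves"]


class CurveParseError(ValueError):
    """Raised when a curve file cannot be parsed."""


@dataclass(frozen=True)
class ReservoirOffset:
    """Local marine reservoir offset DeltaR (14C yr) with its 1-sigma error."""

    delta_r: float = 0.0
    delta_r_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_r_sigma < 0:
            raise ValueError("delta_r_sigma must be >= 0")

    @property
    def is_zero(self) -> bool:
        return self.delta_r == 0.0 and self.delta_r_sigma == 0.0


@dataclass
class CalCurve:
    """A calibration curve on a uniform cal BP grid.

    Attributes
    ----------
    grid : ndarray
        Cal BP years, strictly ascending, uniform step.
    mu : ndarray
        Expected 14C age (yr BP) at each grid point.
    sigma : ndarray
        1-sigma curve error (yr) at each grid point, all >= 0.
    label : str
        Identifier, e.g. "intcal20".
    """

    grid: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("curve grid needs at least two points")
        steps = np.diff(self.grid)
        if not np.all(steps > 0):
            raise ValueError("curve grid must be strictly ascending")
        if not np.allclose(steps, steps[0]):
            raise ValueError("curve grid must be uniform")
        if self.mu.shape != self.grid.shape or self.sigma.shape != self.grid.shape:
            raise ValueError("mu and sigma must match grid length")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be >= 0 everywhere")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def tmin(self) -> float:
        return float(self.grid[0])

    @property
    def tmax(self) -> float:
        return float(self.grid[-1])

    def _check_range(self, t: np.ndarray) -> None:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.tmin) or np.any(t > self.tmax):
            raise ValueError(
                f"query outside curve '{self.label}' range "
                f"[{self.tmin:g}, {self.tmax:g}] cal BP"
            )

    def mu_at(self, t):
        """Interpolated 14C age at cal BP `t`; errors outside the grid range."""
        self._check_range(t)
        return np.interp(t, self.grid, self.mu)

    def sigma_at(self, t):
        """Interpolated 1-sigma curve error at cal BP `t`."""
        self._check_range(t)
        return np.interp(t, self.grid, self.sigma)


def load_curve(path, label: str = "") -> CalCurve:
    """Read a `.14c`-style curve file and resample to a uniform 1-yr grid.

    The dialect is: optional '#'-prefixed header lines, then rows of at least
    three numeric columns (cal BP, 14C age, 1-sigma error), comma- or
    whitespace-separated; extra columns are ignored and row order is irrelevant.
    """
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise CurveParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise CurveParseError(
                    f"{path}: line {lineno}: non-numeric value in {parts[:3]}"
                ) from exc
    if not rows:
        raise CurveParseError(f"{path}: no data rows found")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    # drop duplicated cal BP nodes (keep first occurrence)
    keep = np.concatenate([[True], np.diff(arr[:, 0]) > 0])
    arr = arr[keep]
    if arr.shape[0] < 2:
        raise CurveParseError(f"{path}: need at least two distinct cal BP nodes")
    lo = float(np.ceil(arr[0, 0]))
    hi = float(np.floor(arr[-1, 0]))
    grid = np.arange(lo, hi + 0.5, 1.0)
    mu = np.interp(grid, arr[:, 0], arr[:, 1])
    sigma = np.interp(grid, arr[:, 0], arr[:, 2])
    return CalCurve(grid=grid, mu=mu, sigma=sigma, label=label or str(path))


def mix_curves(
    atm: CalCurve,
    mar: CalCurve,
    fraction_marine: float,
    offset: ReservoirOffset = ReservoirOffset(),
) -> CalCurve:
    """Mix atmospheric and marine curves for a marine-diet fraction F.

    On the intersection of the two grids:

        mu_mix(t)    = (1-F) mu_atm(t) + F (mu_mar(t) + DeltaR)
        sigma_mix(t) = sqrt( ((1-F) s_atm(t))^2
                             + (F sqrt(s_mar(t)^2 + sigma_DeltaR^2))^2 )

    The mean is a linear combination and the scaled error terms add in
    quadrature; DeltaR enters the marine component only. At F=0 this is the
    atmospheric curve, at F=1 the reservoir-shifted marine curve.
    """
    f = float(fraction_marine)
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction_marine must lie in [0, 1]")
    lo = max(atm.tmin, mar.tmin)
    hi = min(atm.tmax, mar.tmax)
    if lo >= hi:
        raise ValueError("atmospheric and marine curves have disjoint grids")
    grid = np.arange(np.ceil(lo), np.floor(hi) + 0.5, 1.0)
    mu_a, s_a = atm.mu_at(grid), atm.sigma_at(grid)
    mu_m, s_m = mar.mu_at(grid), mar.sigma_at(grid)
    mu = (1.0 - f) * mu_a + f * (mu_m + offset.delta_r)
    s_m_tot = np.sqrt(s_m**2 + offset.delta_r_sigma**2)
    sigma = np.sqrt(((1.0 - f) * s_a) ** 2 + (f * s_m_tot) ** 2)
    label = f"mix(F={f:g},dR={offset.delta_r:g})[{atm.label}|{mar.label}]"
    return CalCurve(grid=grid, mu=mu, sigma=sigma, label=label)
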