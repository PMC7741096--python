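"""Monte Carlo LOESS palaeodietary trend from human stable isotopes.

Human bone d13C tracks the marine share of dietary protein (more marine =
less negative).  Each individual's calendar age is uncertain — it comes from
a radiocarbon date calibrated on a mixed marine/atmospheric curve — so the
regression of d13C on age is repeated over Monte Carlo draws from the
calibrated densities: each iteration draws one calendar year per individual,
fits a LOESS smoother, and predicts on a common grid.  The iteration mean is
the trend; 2.5/97.5 percentiles give an envelope that carries both the
calibration and the smoother uncertainty.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._rng import rng_stream
from .calibrate import C14Date, calibrate_date
from .curves import CalCurve, ReservoirOffset

__all__ = ["IsotopeSample", "DietTrend", "mc_loess", "trend_extremum", "read_isotopes"]


@dataclass
class IsotopeSample:
    """One human individual with radiocarbon and stable-isotope measurements."""

    individual_id: str
    cra: float
    error: float
    d13c: float
    d15n: float = float("nan")
    fraction_marine: float = 0.0
    offset: ReservoirOffset = field(default_factory=ReservoirOffset)
    group: str = ""

    def __post_init__(self) -> None:
        if self.error <= 0:
            raise ValueError(f"{self.individual_id}: error must be > 0")
        if not 0.0 <= self.fraction_marine <= 1.0:
            raise ValueError(f"{self.individual_id}: fraction_marine must lie in [0, 1]")
        if not -25.0 <= self.d13c <= -10.0:
            warnings.warn(
                f"{self.individual_id}: d13C {self.d13c:g} outside typical "
                "[-25, -10] permil range",
                stacklevel=2,
            )

    def as_c14(self) -> C14Date:
        return C14Date(
            lab_id=self.individual_id,
            cra=self.cra,
            error=self.error,
            fraction_marine=self.fraction_marine,
            offset=self.offset,
        )


@dataclass
class DietTrend:
    grid: np.ndarray
    mean_d13c: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_mc: int

    def __post_init__(self) -> None:
        bad = self.lower > self.mean_d13c + 1e-12
        bad |= self.upper < self.mean_d13c - 1e-12
        if np.any(bad[np.isfinite(self.mean_d13c)]):
            raise ValueError("envelope must bracket the mean")


def mc_loess(
    samples: list[IsotopeSample],
    atm: CalCurve,
    mar: CalCurve | None = None,
    n_mc: int = 1000,
    span: float = 0.75,
    seed: int = 0,
    grid_step: float = 10.0,
    min_coverage: float = 0.90,
) -> DietTrend:
    """Monte Carlo LOESS regression of d13C on calibrated calendar age.

    Parameters
    ----------
    span : float
        LOESS span (fraction of points in each local fit), in (0, 1].
    min_coverage : float
        The prediction grid is restricted to cells covered by at least this
        fraction of iterations (an iteration covers the range of its drawn
        years; LOESS is not extrapolated).
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if len(samples) < 5:
        raise ValueError("need at least 5 isotope samples")
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")

    dens = [calibrate_date(s.as_c14(), atm, mar) for s in samples]
    n = len(samples)
    years = np.empty((n, n_mc), dtype=float)
    # each individual has its own stream keyed by id, so the result does not
    # depend on the order the samples are supplied in
    for j, (s, d) in enumerate(zip(samples, dens)):
        rng = rng_stream(seed, f"mc-loess/{s.individual_id}")
        cdf = np.cumsum(d.mass)
        cdf /= cdf[-1]
        years[j] = np.interp(rng.random(n_mc), cdf, d.grid)
    d13c = np.array([s.d13c for s in samples], dtype=float)

    lo = np.floor(years.min() / grid_step) * grid_step
    hi = np.ceil(years.max() / grid_step) * grid_step
    grid = np.arange(lo, hi + grid_step / 2, grid_step)

    preds = np.full((n_mc, grid.size), np.nan)
    for i in range(n_mc):
        x = years[:, i]
        fit = lowess(d13c, x, frac=span, it=1, return_sorted=True)
        xmin, xmax = x.min(), x.max()
        m = (grid >= xmin) & (grid <= xmax)
        preds[i, m] = np.interp(grid[m], fit[:, 0], fit[:, 1])

    covered = np.mean(np.isfinite(preds), axis=0) >= min_coverage
    if not covered.any():
        raise ValueError("no grid cell covered by enough iterations")
    grid = grid[covered]
    preds = preds[:, covered]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(preds, axis=0)
        lower, upper = np.nanpercentile(preds, [2.5, 97.5], axis=0)
    return DietTrend(grid=grid, mean_d13c=mean, lower=lower, upper=upper, n_mc=n_mc)


def trend_extremum(trend: DietTrend, mode: str = "max") -> tuple[float, float]:
    """Grid point of extreme mean d13C ("max" = most enriched, most marine);
    ties break toward the older (larger cal BP) end."""
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    vals = trend.mean_d13c
    ext = np.nanmax(vals) if mode == "max" else np.nanmin(vals)
    at = trend.grid[np.isclose(vals, ext)]
    return float(at.max()), float(ext)


def read_isotopes(path) -> list[IsotopeSample]:
    """Read an isotope table CSV: individual_id, cra, error, d13c required;
    d15n, fraction_marine, delta_r, delta_r_sigma, group, site optional."""
    df = pd.read_csv(path)
    need = {"individual_id", "cra", "error", "d13c"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    def get(row, col, default):
        if col in df.columns and not pd.isna(row[col]):
            return row[col]
        return default

    out = []
    for _, row in df.iterrows():
        out.append(
            IsotopeSample(
                individual_id=str(row["individual_id"]),
                cra=float(row["cra"]),
                error=float(row["error"]),
                d13c=float(row["d13c"]),
                d15n=float(get(row, "d15n", float("nan"))),
                fraction_marine=float(get(row, "fraction_marine", 0.0)),
                offset=ReservoirOffset(
                    delta_r=float(get(row, "delta_r", 0.0)),
                    delta_r_sigma=float(get(row, "delta_r_sigma", 0.0)),
                ),
                group=str(get(row, "group", "")),
            )
        )
    return out
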