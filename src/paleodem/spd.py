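"""Summed probability densities (SPDs) with taphonomic correction and
bootstrap confidence envelopes.

The SPD is the pointwise sum of the per-date calibrated densities (each
normalized to unit mass before summation), one date per site phase.  Open-air
sites lose their older deposits to erosion and burial; their partial SPD is
divided by the power-law survival curve of Surovell et al. and rescaled so
the open-air share of total mass is preserved, then added to the uncorrected
SPD of closed sites (caves, rockshelters).

Confidence envelopes come from resampling phase bins with replacement and
re-picking each sampled bin's representative at random among its members, so
intra-phase choice uncertainty enters the envelope.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import rng_stream
from .calibrate import C14Date, CalDensity, density_rows
from .curves import CalCurve
from .phasing import PhaseBin

__all__ = [
    "DensityModel",
    "sum_densities",
    "taphonomic_survival",
    "build_spd",
    "bootstrap_spd",
]

# Surovell et al. (2009) global taphonomic survival model n(t) = a (t + b)^c
TAPHONOMIC_A = 5.726442e6
TAPHONOMIC_B = 2176.4
TAPHONOMIC_C = -1.3925309


@dataclass
class DensityModel:
    """A time series (SPD, KDE, growth rate, or null model) with envelope.

    `mean`, `lower`, `upper` are per-grid-cell values; for kind "spd"/"null"
    they are probability mass per cell, for "kde" probability density per
    year, for "growth" percent per annum.  Empirical quantile envelopes can
    fall on the wrong side of the pointwise mean in far-tail cells where most
    replicates are exactly zero; the constructor widens the envelope minimally
    to contain the mean.  `replicates` (optional) holds the raw bootstrap
    replicate matrix (n_boot x len(grid)) for downstream use.
    """

    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    coverage: float = 0.954
    n_boot: int = 0
    kind: str = "spd"
    replicates: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not 0.0 < self.coverage < 1.0:
            raise ValueError("coverage must lie in (0, 1)")
        for name in ("mean", "lower", "upper"):
            if getattr(self, name).shape != self.grid.shape:
                raise ValueError(f"{name} must match grid length")
        with np.errstate(invalid="ignore"):
            self.lower = np.fmin(self.lower, self.mean)
            self.upper = np.fmax(self.upper, self.mean)

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size > 1 else 1.0


def _default_grid(densities: list[CalDensity], step: float = 1.0) -> np.ndarray:
    lo = min(float(d.grid.min()) for d in densities)
    hi = max(float(d.grid.max()) for d in densities)
    return np.arange(np.floor(lo), np.ceil(hi) + step / 2, step)


def _resample_mass(d: CalDensity, grid: np.ndarray, step: float) -> np.ndarray:
    """Move a per-cell mass vector onto a new uniform grid, conserving mass."""
    dens = np.interp(grid, d.grid, d.mass / d.step, left=0.0, right=0.0) * step
    total = dens.sum()
    if total > 0:
        dens *= d.mass.sum() / total
    return dens


def sum_densities(densities: list[CalDensity], grid: np.ndarray) -> np.ndarray:
    """Pointwise sum of per-date masses on `grid`; total mass = #dates."""
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    if not densities:
        return out
    step = float(grid[1] - grid[0]) if grid.size > 1 else 1.0
    for d in densities:
        out += _resample_mass(d, grid, step)
    return out


def taphonomic_survival(t):
    """Surovell power-law survival weight n(t) = a (t + b)^c, decreasing in t."""
    t = np.asarray(t, dtype=float)
    if np.any(t + TAPHONOMIC_B <= 0):
        raise ValueError("taphonomic model undefined for t + b <= 0")
    out = TAPHONOMIC_A * (t + TAPHONOMIC_B) ** TAPHONOMIC_C
    return out if out.ndim else float(out)


def _site_type_flags(dates: list[C14Date]) -> np.ndarray:
    flags = np.empty(len(dates), dtype=bool)
    for i, d in enumerate(dates):
        if d.site_type == "open_air":
            flags[i] = True
        elif d.site_type == "closed":
            flags[i] = False
        else:  # pragma: no cover - C14Date validates, but guard anyway
            raise ValueError(f"unknown site_type {d.site_type!r}")
    return flags


def _combine(rows: np.ndarray, open_flags: np.ndarray, surv: np.ndarray, correct: bool) -> np.ndarray:
    """Sum rows into an SPD, correcting the open-air share if requested."""
    if not correct or not open_flags.any():
        return rows.sum(axis=0)
    open_sum = rows[open_flags].sum(axis=0)
    corrected = open_sum / surv
    total_corr = corrected.sum()
    if total_corr > 0:
        corrected *= open_flags.sum() / total_corr
    return corrected + rows[~open_flags].sum(axis=0)


def _bin_arrays(bins: list[PhaseBin], dates: dict[str, C14Date]):
    """Flatten bins to member-date lists plus padded member-index lookup."""
    all_dates: list[C14Date] = []
    members: list[list[int]] = []
    rep_row: list[int] = []
    for b in bins:
        idx = []
        for lab in b.member_ids:
            idx.append(len(all_dates))
            all_dates.append(dates[lab])
        members.append(idx)
        rep_row.append(idx[b.member_ids.index(b.representative_id)])
    counts = np.array([len(m) for m in members])
    padded = np.zeros((len(members), counts.max()), dtype=int)
    for i, m in enumerate(members):
        padded[i, : len(m)] = m
    return all_dates, padded, counts, np.array(rep_row)


def build_spd(
    bins: list[PhaseBin],
    dates: dict[str, C14Date],
    atm: CalCurve,
    mar: CalCurve | None = None,
    correct_open_air: bool = True,
    grid: np.ndarray | None = None,
    grid_step: float = 1.0,
) -> DensityModel:
    """SPD of one representative date per phase bin (mean only, no envelope)."""
    reps = [dates[b.representative_id] for b in bins]
    if grid is None:
        lo = min(d.cra - 10 * d.error for d in reps)
        hi = max(d.cra + 10 * d.error for d in reps)
        lo = max(atm.tmin, lo - 500)
        hi = min(atm.tmax, hi + 500)
        grid = np.arange(np.floor(lo), np.ceil(hi) + grid_step / 2, grid_step)
    grid = np.asarray(grid, dtype=float)
    rows = density_rows(reps, atm, mar, grid)
    open_flags = _site_type_flags(reps)
    surv = taphonomic_survival(grid)
    spd = _combine(rows, open_flags, surv, correct_open_air)
    return DensityModel(grid=grid, mean=spd, lower=spd, upper=spd, n_boot=0, kind="spd")


def bootstrap_spd(
    bins: list[PhaseBin],
    dates: dict[str, C14Date],
    atm: CalCurve,
    mar: CalCurve | None = None,
    n_boot: int = 1000,
    coverage: float = 0.954,
    seed: int = 0,
    correct_open_air: bool = True,
    grid: np.ndarray | None = None,
    grid_step: float = 1.0,
    keep_replicates: bool = True,
) -> DensityModel:
    """Bootstrap envelope for the SPD.

    Each replicate resamples phase bins with replacement (same count),
    re-picks each sampled bin's representative uniformly among its members,
    and rebuilds the (taphonomically corrected) SPD; the envelope is the
    pointwise empirical quantile band at the requested coverage.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if len(bins) < 2:
        raise ValueError("need at least 2 phase bins to bootstrap")
    all_dates, padded, counts, _ = _bin_arrays(bins, dates)
    if grid is None:
        lo = min(d.cra - 10 * d.error for d in all_dates)
        hi = max(d.cra + 10 * d.error for d in all_dates)
        lo = max(atm.tmin, lo - 500)
        hi = min(atm.tmax, hi + 500)
        grid = np.arange(np.floor(lo), np.ceil(hi) + grid_step / 2, grid_step)
    grid = np.asarray(grid, dtype=float)
    rows = density_rows(all_dates, atm, mar, grid)
    open_flags = _site_type_flags(all_dates)
    surv = taphonomic_survival(grid)

    rng = rng_stream(seed, "spd-bootstrap")
    n_bins = len(bins)
    reps = np.empty((n_boot, grid.size), dtype=float)
    for b in range(n_boot):
        bin_idx = rng.integers(0, n_bins, size=n_bins)
        pick = padded[bin_idx, (rng.random(n_bins) * counts[bin_idx]).astype(int)]
        reps[b] = _combine(rows[pick], open_flags[pick], surv, correct_open_air)

    alpha = (1.0 - coverage) / 2.0
    lower, upper = np.quantile(reps, [alpha, 1.0 - alpha], axis=0)
    return DensityModel(
        grid=grid,
        mean=reps.mean(axis=0),
        lower=lower,
        upper=upper,
        coverage=coverage,
        n_boot=n_boot,
        kind="spd",
        replicates=reps if keep_replicates else None,
    )
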