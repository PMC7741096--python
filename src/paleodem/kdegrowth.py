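"""Bootstrapped KDE population model and continuous annualized growth rates.

A composite kernel density estimate is built by resampling phase bins with
replacement and drawing ONE calendar year per sampled bin from its
representative's calibrated density, then smoothing the draws with a fixed
Gaussian kernel (default bandwidth 150 yr).  Unlike the SPD, the KDE cancels
calibration-curve noise, which makes its derivative usable.

The annualized growth rate is the logarithmic time derivative of each
replicate KDE,

    r_b(t) = -d log K_b / d tau   (tau = cal BP; x100 for percent per annum)

evaluated by central differences of log K, so an exactly exponential density
yields exactly its exponent.  The sign convention makes growth toward the
present (decreasing cal BP) positive.  Growth phases (sustained spans of
positive growth) are extracted per replicate and summarized as mean +/- sd.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import rng_stream
from .calibrate import C14Date, calibrate_date
from .curves import CalCurve
from .phasing import PhaseBin
from .spd import DensityModel

__all__ = [
    "GrowthPhases",
    "PhaseSummary",
    "kde_model",
    "growth_rate",
    "extract_phases",
    "reliability_floor",
]

KDE_FLOOR = 1e-12


def reliability_floor(n_bins: int, bandwidth: float, min_events: float = 2.0) -> float:
    """Density floor below which a growth estimate is unreliable.

    The growth rate is only interpretable where the record actually has
    dates: a cell whose KDE density implies fewer than `min_events` expected
    dates within +/- one bandwidth is dominated by kernel tails and shot
    noise, and its log-derivative spikes spuriously at the edges of the
    dated record.  Returns the per-year density threshold
    min_events / (2 * bandwidth * n_bins).
    """
    if n_bins <= 0 or bandwidth <= 0:
        raise ValueError("n_bins and bandwidth must be positive")
    return min_events / (2.0 * bandwidth * n_bins)


@dataclass
class PhaseSummary:
    """One growth phase: mean +/- sd over bootstrap replicates."""

    start: float
    start_sd: float
    duration: float
    duration_sd: float
    max_rate: float
    max_rate_sd: float
    t_max_rate: float
    t_max_rate_sd: float
    t_pop_max: float
    t_pop_max_sd: float
    n_replicates: int
    support: float  # fraction of replicates in which the phase was found

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class GrowthPhases:
    phases: list[PhaseSummary] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.phases)

    def __iter__(self):
        return iter(self.phases)

    def to_dict(self) -> dict:
        return {"phases": [p.to_dict() for p in self.phases]}


def kde_model(
    bins: list[PhaseBin],
    dates: dict[str, C14Date],
    atm: CalCurve,
    mar: CalCurve | None = None,
    bandwidth: float = 150.0,
    n_boot: int = 1000,
    coverage: float = 0.954,
    seed: int = 0,
    grid: np.ndarray | None = None,
    grid_step: float = 10.0,
) -> DensityModel:
    """Bootstrapped Gaussian KDE of phase-bin calendar ages.

    Each replicate resamples bins with replacement and draws one calendar
    year per sampled bin from its representative's calibrated density; each
    replicate density is renormalized to unit integral on the grid.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if len(bins) < 2:
        raise ValueError("need at least 2 phase bins")

    dens = [calibrate_date(dates[b.representative_id], atm, mar) for b in bins]
    if grid is None:
        lo = min(float(d.grid.min()) for d in dens) - 4 * bandwidth
        hi = max(float(d.grid.max()) for d in dens) + 4 * bandwidth
        grid = np.arange(np.floor(lo), np.ceil(hi) + grid_step / 2, grid_step)
    grid = np.asarray(grid, dtype=float)
    step = float(grid[1] - grid[0])

    rng = rng_stream(seed, "kde-bootstrap")
    n_bins = len(bins)
    # one calendar draw per (bin, replicate), inverse-CDF per bin
    years = np.empty((n_bins, n_boot), dtype=float)
    for j, d in enumerate(dens):
        cdf = np.cumsum(d.mass)
        cdf /= cdf[-1]
        years[j] = np.interp(rng.random(n_boot), cdf, d.grid)

    reps = np.empty((n_boot, grid.size), dtype=float)
    inv2h2 = 1.0 / (2.0 * bandwidth**2)
    for b in range(n_boot):
        bin_idx = rng.integers(0, n_bins, size=n_bins)
        draws = years[bin_idx, b]
        k = np.exp(-((grid[:, None] - draws[None, :]) ** 2) * inv2h2).sum(axis=1)
        total = k.sum() * step
        reps[b] = k / total if total > 0 else k

    alpha = (1.0 - coverage) / 2.0
    lower, upper = np.quantile(reps, [alpha, 1.0 - alpha], axis=0)
    return DensityModel(
        grid=grid,
        mean=reps.mean(axis=0),
        lower=lower,
        upper=upper,
        coverage=coverage,
        n_boot=n_boot,
        kind="kde",
        replicates=reps,
    )


def growth_rate(
    kde: DensityModel | np.ndarray,
    grid: np.ndarray | None = None,
    coverage: float | None = None,
    floor: float = KDE_FLOOR,
) -> DensityModel:
    """Annualized growth-rate series from bootstrapped KDE replicates.

    Accepts the DensityModel returned by `kde_model` (using its replicate
    matrix) or a raw (n_boot, n_grid) array plus `grid`.  Cells where a
    replicate density is below `floor` are masked (NaN) in that replicate;
    pass `floor=reliability_floor(...)` to additionally mask cells where the
    record is too sparse for the derivative to mean anything.
    """
    if isinstance(kde, DensityModel):
        if kde.replicates is None:
            raise ValueError("KDE model carries no replicates")
        reps = kde.replicates
        grid = kde.grid
        if coverage is None:
            coverage = kde.coverage
    else:
        reps = np.atleast_2d(np.asarray(kde, dtype=float))
        if grid is None:
            raise ValueError("grid required when passing a raw replicate array")
        grid = np.asarray(grid, dtype=float)
        if coverage is None:
            coverage = 0.954
    steps = np.diff(grid)
    if not (np.all(steps > 0) and np.allclose(steps, steps[0])):
        raise ValueError("growth rate requires a uniform ascending grid")
    step = float(steps[0])

    logk = np.where(reps > floor, np.log(np.maximum(reps, floor)), np.nan)
    # r = -d log K / d tau, percent per annum
    r = -np.gradient(logk, step, axis=1) * 100.0

    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(r, axis=0)
        alpha = (1.0 - coverage) / 2.0
        all_nan = np.all(np.isnan(r), axis=0)
        lower = np.full(grid.size, np.nan)
        upper = np.full(grid.size, np.nan)
        if not all_nan.all():
            lower[~all_nan], upper[~all_nan] = np.nanquantile(
                r[:, ~all_nan], [alpha, 1.0 - alpha], axis=0
            )
    return DensityModel(
        grid=grid,
        mean=mean,
        lower=lower,
        upper=upper,
        coverage=coverage,
        n_boot=reps.shape[0],
        kind="growth",
        replicates=r,
    )


def _phases_of(r: np.ndarray, grid: np.ndarray, min_span: float) -> list[dict]:
    """Maximal spans of positive growth sustained >= min_span years.

    Returns dicts with start (old end), t_pop_max (young end), duration,
    max_rate, t_max_rate; NaN cells break spans.
    """
    ok = np.isfinite(r) & (r > 0)
    out = []
    i = 0
    n = ok.size
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            span = float(grid[j] - grid[i])
            if span >= min_span:
                seg = r[i : j + 1]
                k = int(np.argmax(seg))
                out.append(
                    {
                        "start": float(grid[j]),
                        "t_pop_max": float(grid[i]),
                        "duration": span,
                        "max_rate": float(seg[k]),
                        "t_max_rate": float(grid[i + k]),
                    }
                )
            i = j + 1
        else:
            i += 1
    return sorted(out, key=lambda p: -p["start"])


def _overlap(a: dict, b: dict) -> float:
    return max(0.0, min(a["start"], b["start"]) - max(a["t_pop_max"], b["t_pop_max"]))


def extract_phases(growth: DensityModel, min_phase_span: float = 200.0) -> GrowthPhases:
    """Growth-phase descriptors with replicate uncertainties.

    Phases are located on the mean growth curve; each replicate's phases are
    matched to them by interval overlap and the descriptors summarized as
    mean +/- sd across matched replicates.
    """
    if growth.kind != "growth":
        raise ValueError("extract_phases expects a growth-rate DensityModel")
    mean_phases = _phases_of(growth.mean, growth.grid, min_phase_span)
    if not mean_phases:
        return GrowthPhases([])
    reps = growth.replicates
    if reps is None:
        reps = growth.mean[None, :]
    matched: list[list[dict]] = [[] for _ in mean_phases]
    for b in range(reps.shape[0]):
        rp = _phases_of(reps[b], growth.grid, min_phase_span)
        best: dict[int, dict] = {}
        for p in rp:
            ovs = [_overlap(p, q) for q in mean_phases]
            qi = int(np.argmax(ovs))
            if ovs[qi] <= 0:
                continue
            if qi not in best or _overlap(p, mean_phases[qi]) > _overlap(best[qi], mean_phases[qi]):
                best[qi] = p
        for qi, p in best.items():
            matched[qi].append(p)

    out = []
    for q, plist in zip(mean_phases, matched):
        if not plist:
            continue

        def stats(key):
            vals = np.array([p[key] for p in plist], dtype=float)
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            return float(vals.mean()), sd

        s, s_sd = stats("start")
        d, d_sd = stats("duration")
        m, m_sd = stats("max_rate")
        tm, tm_sd = stats("t_max_rate")
        tp, tp_sd = stats("t_pop_max")
        out.append(
            PhaseSummary(
                start=s,
                start_sd=s_sd,
                duration=d,
                duration_sd=d_sd,
                max_rate=m,
                max_rate_sd=m_sd,
                t_max_rate=tm,
                t_max_rate_sd=tm_sd,
                t_pop_max=tp,
                t_pop_max_sd=tp_sd,
                n_replicates=len(plist),
                support=len(plist) / reps.shape[0],
            )
        )
    return GrowthPhases(sorted(out, key=lambda p: -p.start))
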