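"""Synthetic datasets with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a Late Glacial / Early
Holocene coastal hunter-gatherer radiocarbon record:

* event calendar dates drawn from a piecewise-exponential population curve
  with a stadial crash and two Holocene booms (each curve segment has an
  exact closed-form growth rate, giving the growth model a hard target);
* open-air versus closed (cave/rockshelter) site types, with open-air events
  thinned by the same taphonomic survival law the pipeline corrects for;
* site coordinates from a Gaussian cluster whose spatial scale follows a
  time-varying schedule (dispersal and contraction episodes);
* synthetic wiggly calibration curves (atmospheric, and marine with a
  ~400-yr reservoir) plus per-date lab errors, so determinations are made by
  inverting the calibration mapping;
* a human stable-isotope series whose d13C ramps to a marine-diet peak and
  reverses, with marine fraction tied to d13C;
* an environmental proxy series correlated with the population curve through
  a gain plus AR(1) noise.

All tabular outputs use the exact CSV schemas the pipeline reads, and a
ground-truth record carries everything needed to score recovery.  Synthetic
site coordinates are planar kilometres (use metric="projected_euclidean").
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import rng_stream
from .curves import CalCurve, ReservoirOffset, mix_curves
from .spd import taphonomic_survival

__all__ = [
    "PopulationScenario",
    "SyntheticDataset",
    "synthetic_curves",
    "write_curve",
    "curve_level",
    "sample_events",
    "uncalibrate",
    "make_dataset",
]

# Default truth curve: (cal BP, relative level).  Segment rates follow from
# r = ln(L_young/L_old) / (t_old - t_young).  Each boom ramps its growth rate
# up to a mid-phase maximum and back down (as real populations do), so the
# phase descriptors are: boom 1 starting 10300 cal BP with maximum rate
# 0.40 %/yr (reached 10100-9800) and population maximum at 9400; boom 2
# starting 8700 with maximum 0.25 %/yr (8400-8100) and maximum at 7750.
#   14000-12800  +0.025 %/yr   (mild interstadial growth)
#   12800-11700  -0.078 %/yr   (stadial crash)
#   11700-10300  -0.007 %/yr   (flat, slightly declining recovery)
#   10300-10100  +0.200 %/yr   (boom 1 onset)
#   10100- 9800  +0.400 %/yr   (boom 1 maximum)
#    9800- 9400  +0.150 %/yr   (boom 1 tail)
#    9400- 8700  -0.200 %/yr   (decline)
#    8700- 8400  +0.120 %/yr   (boom 2 onset)
#    8400- 8100  +0.250 %/yr   (boom 2 maximum)
#    8100- 7750  +0.100 %/yr   (boom 2 tail)
#    7750- 7000  -0.250 %/yr   (terminal decline)
DEFAULT_BREAKPOINTS = (
    (14000.0, 1.0),
    (12800.0, 1.35),
    (11700.0, 0.57),
    (10300.0, 0.52),
    (10100.0, 0.776),
    (9800.0, 2.576),
    (9400.0, 4.694),
    (8700.0, 1.158),
    (8400.0, 1.660),
    (8100.0, 3.514),
    (7750.0, 4.987),
    (7000.0, 0.765),
)

# Spatial scale (km sd of the site cluster) through time: tight interstadial
# clustering (~28 km sd = ~50 km mean inter-site distance), fivefold stadial
# dispersal, then monotonic Holocene contraction (~200 -> ~100 km mean).
DEFAULT_CLUSTERING = (
    (15000.0, 28.0),
    (12800.0, 28.0),
    (11500.0, 140.0),
    (10500.0, 113.0),
    (7500.0, 56.0),
    (7000.0, 56.0),
)


@dataclass
class PopulationScenario:
    """Ground-truth scenario for the synthetic generator.

    diet_trend is (peak cal BP, peak d13C, baseline d13C, noise sd);
    proxy_link is (gain, noise sd, AR1 coefficient).
    """

    breakpoints: tuple = DEFAULT_BREAKPOINTS
    n_dates: int = 300
    open_air_fraction: float = 0.5
    error_distribution: tuple[float, float] = (3.7, 0.3)  # log-mean, log-sd of lab error
    site_count: int = 60
    clustering_schedule: tuple = DEFAULT_CLUSTERING
    diet_trend: tuple[float, float, float, float] = (7800.0, -14.5, -19.5, 0.6)
    n_isotopes: int = 54
    diet_window: tuple[float, float] = (8500.0, 7000.0)
    proxy_link: tuple[float, float, float] = (1.0, 0.25, 0.6)
    contaminant_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.breakpoints]
        lv = [l for _, l in self.breakpoints]
        if any(l <= 0 for l in lv):
            raise ValueError("curve levels must be > 0")
        if not all(a > b for a, b in zip(ts, ts[1:])):
            raise ValueError("breakpoints must be strictly descending in cal BP")
        if not 0.0 <= self.open_air_fraction <= 1.0:
            raise ValueError("open_air_fraction must lie in [0, 1]")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant_fraction must lie in [0, 1)")

    @property
    def t_old(self) -> float:
        return float(self.breakpoints[0][0])

    @property
    def t_young(self) -> float:
        return float(self.breakpoints[-1][0])

    def truth_phases(self) -> list[dict]:
        """Growth phases of the truth curve: maximal runs of contiguous
        positive-rate segments, with the run's maximum rate (% per annum)."""
        segs = []
        for (t1, l1), (t2, l2) in zip(self.breakpoints, self.breakpoints[1:]):
            segs.append((t1, t2, float(np.log(l2 / l1) / (t1 - t2))))
        out = []
        i = 0
        while i < len(segs):
            if segs[i][2] > 0:
                j = i
                while j + 1 < len(segs) and segs[j + 1][2] > 0:
                    j += 1
                run = segs[i : j + 1]
                best = max(run, key=lambda s: s[2])
                out.append(
                    {
                        "start": run[0][0],
                        "t_pop_max": run[-1][1],
                        "duration": run[0][0] - run[-1][1],
                        "rate_pct": 100.0 * best[2],
                        "t_max_rate_old": best[0],
                        "t_max_rate_young": best[1],
                    }
                )
                i = j + 1
            else:
                i += 1
        return out

    def truth(self) -> dict:
        return {
            "breakpoints": [list(bp) for bp in self.breakpoints],
            "phases": self.truth_phases(),
            "diet_peak_calbp": self.diet_trend[0],
            "clustering_schedule": [list(c) for c in self.clustering_schedule],
            "n_clean_dates": self.n_dates,
            "seed": self.seed,
        }


@dataclass
class SyntheticDataset:
    dates: pd.DataFrame
    isotopes: pd.DataFrame
    proxy: pd.DataFrame
    truth: dict
    atm: CalCurve
    mar: CalCurve


def curve_level(scn: PopulationScenario, t) -> np.ndarray:
    """Truth population level at cal BP t (piecewise log-linear)."""
    t = np.asarray(t, dtype=float)
    ts = np.array([bp[0] for bp in scn.breakpoints])[::-1]
    ls = np.log([bp[1] for bp in scn.breakpoints])[::-1]
    return np.exp(np.interp(t, ts, ls))


def synthetic_curves(t_min: float = 5500.0, t_max: float = 16000.0) -> tuple[CalCurve, CalCurve]:
    """A wiggly atmospheric curve and a reservoir-shifted marine companion.

    The atmospheric curve is calendar age plus two sinusoidal wiggle trains
    (kept weak enough that mu stays monotone); the marine curve carries a
    400-yr global reservoir and damped wiggles, with larger curve error.
    """
    grid = np.arange(float(t_min), float(t_max) + 0.5, 1.0)
    frac = (grid - grid[0]) / (grid[-1] - grid[0])
    mu_atm = (
        grid
        + 120.0 * np.sin(2 * np.pi * grid / 2300.0 + 0.4)
        + 35.0 * np.sin(2 * np.pi * grid / 610.0 + 1.7)
    )
    sigma_atm = 8.0 + 4.0 * frac
    mu_mar = grid + 400.0 + 90.0 * np.sin(2 * np.pi * grid / 2300.0 + 0.7)
    sigma_mar = 12.0 + 5.0 * frac
    atm = CalCurve(grid=grid, mu=mu_atm, sigma=sigma_atm, label="synthetic-atm")
    mar = CalCurve(grid=grid, mu=mu_mar, sigma=sigma_mar, label="synthetic-marine")
    return atm, mar


def write_curve(curve: CalCurve, path) -> None:
    """Write a curve in the `.14c` dialect (cal BP, 14C age, error), oldest first."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {curve.label}\n# cal BP, 14C age, 1-sigma error\n")
        for t, m, s in zip(curve.grid[::-1], curve.mu[::-1], curve.sigma[::-1]):
            fh.write(f"{t:.0f},{m:.2f},{s:.2f}\n")


def _inverse_cdf_sampler(lattice: np.ndarray, weights: np.ndarray):
    cdf = np.cumsum(weights)
    if cdf[-1] <= 0:
        raise ValueError("population curve has zero total mass")
    cdf = cdf / cdf[-1]

    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.interp(rng.random(n), cdf, lattice)

    return draw


def _cluster_sd(scn: PopulationScenario, t) -> np.ndarray:
    ts = np.array([c[0] for c in scn.clustering_schedule])[::-1]
    sds = np.array([c[1] for c in scn.clustering_schedule])[::-1]
    return np.interp(np.asarray(t, dtype=float), ts, sds)


def sample_events(scn: PopulationScenario, seed: int | None = None) -> pd.DataFrame:
    """Dated depositional events: year, site assignment, type, coordinates.

    Event years are drawn with probability proportional to curve(t), thinned
    by the taphonomic survival law for open-air events (so the record the
    pipeline sees is biased exactly the way its correction assumes).  Sites
    are Gaussian-scattered around a common centre with the sd the clustering
    schedule prescribes at each site's characteristic age; events attach to a
    site of their type with weight decaying in |event year - site age|.
    """
    rng = rng_stream(scn.seed if seed is None else seed, "events")
    lattice = np.arange(scn.t_young, scn.t_old + 0.5, 1.0)
    lvl = curve_level(scn, lattice)
    draw_closed = _inverse_cdf_sampler(lattice, lvl)
    draw_open = _inverse_cdf_sampler(lattice, lvl * taphonomic_survival(lattice))

    n_open_sites = int(round(scn.open_air_fraction * scn.site_count))
    types = np.array(["open_air"] * n_open_sites + ["closed"] * (scn.site_count - n_open_sites))
    rng.shuffle(types)
    char = np.empty(scn.site_count)
    char[types == "closed"] = draw_closed(rng, int((types == "closed").sum()))
    char[types == "open_air"] = draw_open(rng, int((types == "open_air").sum()))
    sd = _cluster_sd(scn, char)
    x = rng.normal(0.0, sd)
    y = rng.normal(0.0, sd)
    site_ids = np.array([f"S{i + 1:03d}" for i in range(scn.site_count)])

    is_open = rng.random(scn.n_dates) < scn.open_air_fraction
    years = np.empty(scn.n_dates)
    years[is_open] = draw_open(rng, int(is_open.sum()))
    years[~is_open] = draw_closed(rng, int((~is_open).sum()))

    rows = []
    for k in range(scn.n_dates):
        want = "open_air" if is_open[k] else "closed"
        cand = np.flatnonzero(types == want)
        if cand.size == 0:
            cand = np.arange(scn.site_count)
        w = np.exp(-0.5 * ((years[k] - char[cand]) / 300.0) ** 2) + 1e-9
        j = int(rng.choice(cand, p=w / w.sum()))
        rows.append((years[k], site_ids[j], types[j], x[j], y[j]))
    return pd.DataFrame(rows, columns=["year", "site_id", "site_type", "x_km", "y_km"])


def uncalibrate(
    years,
    curve: CalCurve,
    lab_errors,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert calibration: draw CRAs ~ N(mu(year), sqrt(sigma(year)^2 + err^2)).

    Returns (cra, error) arrays; CRAs are rounded to the nearest year.
    """
    years = np.atleast_1d(np.asarray(years, dtype=float))
    errs = np.broadcast_to(np.asarray(lab_errors, dtype=float), years.shape).astype(float)
    mu = curve.mu_at(years)  # errors if out of range
    sig = curve.sigma_at(years)
    cra = np.rint(rng.normal(mu, np.sqrt(sig**2 + errs**2)))
    return cra, errs


def _lab_errors(scn: PopulationScenario, rng: np.random.Generator, n: int) -> np.ndarray:
    logm, logsd = scn.error_distribution
    return np.clip(np.rint(rng.lognormal(logm, logsd, size=n)), 15.0, 150.0)


def make_dataset(
    scn: PopulationScenario,
    atm: CalCurve | None = None,
    mar: CalCurve | None = None,
    outdir=None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Emit the full synthetic input set (dates, isotopes, proxy, truth).

    If `outdir` is given, writes dates.csv, isotopes.csv, proxy.csv,
    truth.json, atm.14c and marine.14c there.
    """
    run_seed = scn.seed if seed is None else seed
    if atm is None or mar is None:
        lo = min(scn.t_young, scn.diet_window[1]) - 800.0
        hi = max(scn.t_old, scn.diet_window[0]) + 1200.0
        a, m = synthetic_curves(lo, hi)
        atm = atm or a
        mar = mar or m

    events = sample_events(scn, seed=run_seed)
    rng = rng_stream(run_seed, "measurement")
    errs = _lab_errors(scn, rng, len(events))
    cras, errs = uncalibrate(events["year"].to_numpy(), atm, errs, rng)

    df = pd.DataFrame(
        {
            "lab_id": [f"D{k + 1:04d}" for k in range(len(events))],
            "site_id": events["site_id"],
            "site_name": events["site_id"],
            "cra": cras,
            "error": errs,
            "site_type": events["site_type"],
            "lon": events["x_km"],
            "lat": events["y_km"],
            "fraction_marine": 0.0,
            "delta_r": 0.0,
            "delta_r_sigma": 0.0,
            "context_flag": "secure",
        }
    )

    # contaminants the screening stage must remove: inflated errors or
    # insecure archaeological association
    n_c = int(round(scn.contaminant_fraction * scn.n_dates))
    if n_c:
        crng = rng_stream(run_seed, "contaminants")
        lattice = np.arange(scn.t_young, scn.t_old + 0.5, 1.0)
        draw = _inverse_cdf_sampler(lattice, curve_level(scn, lattice))
        yrs = draw(crng, n_c)
        big_err = crng.uniform(210.0, 400.0, size=n_c)
        insecure = crng.random(n_c) < 0.5
        errs_c = np.where(insecure, 80.0, big_err)
        cras_c, errs_c = uncalibrate(yrs, atm, errs_c, crng)
        host = df.sample(n=n_c, random_state=int(crng.integers(2**31)))
        extra = pd.DataFrame(
            {
                "lab_id": [f"X{k + 1:04d}" for k in range(n_c)],
                "site_id": host["site_id"].to_numpy(),
                "site_name": host["site_id"].to_numpy(),
                "cra": cras_c,
                "error": np.rint(errs_c),
                "site_type": host["site_type"].to_numpy(),
                "lon": host["lon"].to_numpy(),
                "lat": host["lat"].to_numpy(),
                "fraction_marine": 0.0,
                "delta_r": 0.0,
                "delta_r_sigma": 0.0,
                "context_flag": np.where(insecure, "insecure", "secure"),
            }
        )
        df = pd.concat([df, extra], ignore_index=True)

    isotopes = _make_isotopes(scn, atm, mar, run_seed)
    proxy = _make_proxy(scn, run_seed)
    truth = scn.truth()

    ds = SyntheticDataset(dates=df, isotopes=isotopes, proxy=proxy, truth=truth, atm=atm, mar=mar)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "dates.csv", index=False)
        isotopes.to_csv(outdir / "isotopes.csv", index=False)
        proxy.to_csv(outdir / "proxy.csv", index=False)
        with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=2)
        write_curve(atm, outdir / "atm.14c")
        write_curve(mar, outdir / "marine.14c")
    return ds


def _make_isotopes(scn: PopulationScenario, atm: CalCurve, mar: CalCurve, seed: int) -> pd.DataFrame:
    rng = rng_stream(seed, "isotopes")
    peak_t, peak_c, base_c, noise = scn.diet_trend
    old, young = scn.diet_window
    lattice = np.arange(young, old + 0.5, 1.0)
    draw = _inverse_cdf_sampler(lattice, curve_level(scn, lattice))
    years = draw(rng, scn.n_isotopes)
    half_width = max(old - peak_t, peak_t - young)
    ramp = np.clip(1.0 - np.abs(years - peak_t) / half_width, 0.0, 1.0)
    d13c = base_c + (peak_c - base_c) * ramp + rng.normal(0.0, noise, scn.n_isotopes)
    d13c = np.clip(d13c, -24.5, -10.5)
    # marine fraction from d13C between terrestrial (-21) and marine (-12) endmembers
    frac = np.clip((d13c - (-21.0)) / 9.0, 0.0, 1.0)
    d15n = 6.0 + 8.0 * frac + rng.normal(0.0, 0.5, scn.n_isotopes)
    offset = ReservoirOffset(95.0, 15.0)

    errs = _lab_errors(scn, rng, scn.n_isotopes)
    cras = np.empty(scn.n_isotopes)
    for i in range(scn.n_isotopes):
        mixed = mix_curves(atm, mar, float(frac[i]), offset)
        c, _ = uncalibrate(years[i], mixed, errs[i], rng)
        cras[i] = float(c[0])
    group = np.where(frac >= np.median(frac), "Muge", "Sado")
    return pd.DataFrame(
        {
            "individual_id": [f"H{k + 1:03d}" for k in range(scn.n_isotopes)],
            "site": group,
            "group": group,
            "cra": cras,
            "error": errs,
            "d13c": np.round(d13c, 2),
            "d15n": np.round(d15n, 2),
            "fraction_marine": np.round(frac, 3),
            "delta_r": offset.delta_r,
            "delta_r_sigma": offset.delta_r_sigma,
        }
    )


def _make_proxy(scn: PopulationScenario, seed: int) -> pd.DataFrame:
    rng = rng_stream(seed, "proxy")
    gain, noise, ar1 = scn.proxy_link
    t = np.arange(scn.t_young, scn.t_old + 0.5, 20.0)
    lvl = np.log(curve_level(scn, t))
    # 400-yr running mean, then standardize
    half = 10  # 400 yr / (2 * 20 yr)
    csum = np.concatenate([[0.0], np.cumsum(lvl)])
    lo = np.maximum(np.arange(t.size) - half, 0)
    hi = np.minimum(np.arange(t.size) + half + 1, t.size)
    sm = (csum[hi] - csum[lo]) / (hi - lo)
    sd = sm.std()
    sm = (sm - sm.mean()) / sd if sd > 0 else sm - sm.mean()
    eps = np.empty(t.size)
    eps[0] = rng.normal(0.0, noise)
    for i in range(1, t.size):
        eps[i] = ar1 * eps[i - 1] + rng.normal(0.0, noise)
    return pd.DataFrame({"t_calBP": t, "value": gain * sm + eps})
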