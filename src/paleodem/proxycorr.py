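"""Rank correlation between the population proxy and environmental series.

Population and proxy (e.g. sea-surface temperature, ice-core d18O) series
are linearly interpolated onto a common 50-yr lattice over their overlap;
Spearman's rho is computed on the full overlap and in sliding 500-yr windows
stepped at 50-yr intervals.  No windowed significance testing is attempted:
strong autocorrelation makes naive p-values invalid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .spd import DensityModel

__all__ = ["ProxySeries", "WindowedCorrelation", "running_mean", "spearman_windowed", "read_proxy"]


@dataclass
class ProxySeries:
    t: np.ndarray       # cal BP, strictly monotone
    value: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.value.shape:
            raise ValueError("t and value must be 1-d arrays of equal length")
        if self.t.size == 0:
            raise ValueError("empty proxy series")
        d = np.diff(self.t)
        if self.t.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("t must be strictly monotone")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("proxy values must be finite")

    def ascending(self) -> "ProxySeries":
        if self.t.size > 1 and self.t[1] < self.t[0]:
            return ProxySeries(self.t[::-1].copy(), self.value[::-1].copy(), self.label)
        return self


@dataclass
class WindowedCorrelation:
    centers: np.ndarray
    rho: np.ndarray     # NaN where the window has < 3 lattice points
    n: np.ndarray
    overall_rho: float


def running_mean(series: ProxySeries, width: float = 400.0) -> ProxySeries:
    """Centered moving average over a `width`-year time window (truncated at
    the edges); windows are in time units, not sample counts."""
    if width <= 0:
        raise ValueError("width must be > 0")
    s = series.ascending()
    t, v = s.t, s.value
    half = width / 2.0
    csum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return ProxySeries(t=t.copy(), value=out, label=f"{series.label} ({width:g}-yr mean)")


def spearman_windowed(
    pop: DensityModel,
    proxy: ProxySeries,
    window: float = 500.0,
    step: float = 50.0,
) -> WindowedCorrelation:
    """Spearman rho of population vs proxy, overall and in sliding windows."""
    prox = proxy.ascending()
    lo = max(float(pop.grid.min()), float(prox.t.min()))
    hi = min(float(pop.grid.max()), float(prox.t.max()))
    if lo >= hi:
        raise ValueError("population and proxy series do not overlap in time")
    lattice = np.arange(np.ceil(lo / step) * step, hi + step / 2, step)
    if lattice.size < 3:
        raise ValueError("overlap too short for correlation")
    p = np.interp(lattice, pop.grid, pop.mean)
    x = np.interp(lattice, prox.t, prox.value)
    overall = float(spearmanr(p, x).statistic)

    half = window / 2.0
    rho = np.full(lattice.size, np.nan)
    n = np.zeros(lattice.size, dtype=int)
    for k, c in enumerate(lattice):
        m = np.abs(lattice - c) <= half + 1e-9
        n[k] = int(m.sum())
        if n[k] >= 3:
            rho[k] = float(spearmanr(p[m], x[m]).statistic)
    return WindowedCorrelation(centers=lattice, rho=rho, n=n, overall_rho=overall)


def read_proxy(path, label: str = "") -> ProxySeries:
    """Read a proxy CSV with columns t_calBP, value (extra columns ignored)."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    tcol = cols.get("t_calbp") or cols.get("calbp") or df.columns[0]
    vcol = cols.get("value") or df.columns[1]
    return ProxySeries(
        t=df[tcol].to_numpy(float), value=df[vcol].to_numpy(float), label=label or str(path)
    )
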