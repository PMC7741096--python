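"""Settlement-density proxy: mean pairwise inter-site distance through time.

A first-order point-pattern summary: in sliding time windows (default 500 yr,
stepped at 50 yr), the arithmetic mean of all pairwise distances between
sites occupied in the window.  Falling mean distance indicates clustering of
settlement, rising distance dispersal.  A LOESS track summarizes the trend.

A site counts as occupied in a window when at least one of its phase
representatives has its median calibrated age inside the window — a cheap,
deterministic rule that is adequate because the windows are wide relative to
calibration uncertainty.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from statsmodels.nonparametric.smoothers_lowess import lowess

from .calibrate import C14Date
from .phasing import PhaseBin

__all__ = ["DistanceSeries", "site_occupancy", "mean_pairwise_distance", "distance_series"]

EARTH_RADIUS_KM = 6371.0088
METRICS = ("projected_euclidean", "haversine")


@dataclass
class DistanceSeries:
    centers: np.ndarray          # cal BP window centers
    mean_distance: np.ndarray    # km; NaN where < 2 sites occupied
    n_sites: np.ndarray
    smoothed: np.ndarray         # LOESS of mean_distance; NaN where undefined


def site_occupancy(
    bins: list[PhaseBin],
    medians: dict[str, float],
    window: tuple[float, float],
) -> set[str]:
    """Site ids with >= 1 phase representative median inside [young, old]."""
    old, young = float(window[0]), float(window[1])
    if not old > young:
        raise ValueError("window must be (old, young) with old > young")
    out = set()
    for b in bins:
        m = medians[b.representative_id]
        if young <= m <= old:
            out.add(b.site_id)
    return out


def _haversine_pairs(lonlat: np.ndarray) -> np.ndarray:
    lon = np.radians(lonlat[:, 0])
    lat = np.radians(lonlat[:, 1])
    i, j = np.triu_indices(len(lon), k=1)
    dlat = lat[j] - lat[i]
    dlon = lon[j] - lon[i]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat[i]) * np.cos(lat[j]) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def mean_pairwise_distance(coords, metric: str = "haversine") -> float:
    """Mean over all unordered site pairs; NaN if fewer than 2 sites.

    `coords` is an (n, 2) array: (x_km, y_km) for "projected_euclidean" or
    (lon, lat) in decimal degrees for "haversine".
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    if len(coords) < 2:
        return float("nan")
    if metric == "projected_euclidean":
        return float(pdist(coords).mean())
    if metric == "haversine":
        return float(_haversine_pairs(coords).mean())
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def _site_coords(bins: list[PhaseBin], dates: dict[str, C14Date]) -> dict[str, tuple[float, float]]:
    coords: dict[str, tuple[float, float]] = {}
    for b in bins:
        if b.site_id in coords:
            continue
        for lab in b.member_ids:
            d = dates[lab]
            if np.isfinite(d.lon) and np.isfinite(d.lat):
                coords[b.site_id] = (d.lon, d.lat)
                break
    return coords


def distance_series(
    bins: list[PhaseBin],
    dates: dict[str, C14Date],
    medians: dict[str, float],
    window_len: float = 500.0,
    step: float = 50.0,
    loess_span: float = 0.4,
    metric: str = "haversine",
) -> DistanceSeries:
    """Mean inter-site distance in sliding windows on a regular step lattice."""
    site_xy = _site_coords(bins, dates)
    meds = [medians[b.representative_id] for b in bins]
    if not meds:
        raise ValueError("no phase bins supplied")
    lo = np.ceil(min(meds) / step) * step
    hi = np.floor(max(meds) / step) * step
    centers = np.arange(lo, hi + step / 2, step)

    mean_d = np.full(centers.size, np.nan)
    n_sites = np.zeros(centers.size, dtype=int)
    half = window_len / 2.0
    for k, c in enumerate(centers):
        occ = site_occupancy(bins, medians, (c + half, c - half))
        occ = [s for s in sorted(occ) if s in site_xy]
        n_sites[k] = len(occ)
        if len(occ) >= 2:
            xy = np.array([site_xy[s] for s in occ], dtype=float)
            mean_d[k] = mean_pairwise_distance(xy, metric=metric)

    smoothed = np.full(centers.size, np.nan)
    ok = np.isfinite(mean_d)
    if ok.sum() >= 3:
        fit = lowess(mean_d[ok], centers[ok], frac=loess_span, it=1, return_sorted=True)
        smoothed[ok] = np.interp(centers[ok], fit[:, 0], fit[:, 1])
    elif ok.any():
        smoothed[ok] = mean_d[ok]
    return DistanceSeries(centers=centers, mean_distance=mean_d, n_sites=n_sites, smoothed=smoothed)
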