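"""Screening and site-phase binning.

Heavily sampled sites would otherwise dominate the summed probability signal,
so dates from each site are reduced to one representative per "site phase" —
a cluster of dates spanning no more than one intergenerational period
(default 30 years).  Clustering is agglomerative with complete linkage on the
absolute difference of median calibrated ages, so the guaranteed intra-phase
diameter matches the phase length h.  The representative of each phase is
chosen uniformly at random from its members under a dedicated seeded stream,
so downstream bootstrap seeding never perturbs the binning.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from ._rng import rng_stream
from .calibrate import C14Date, cal_medians
from .curves import CalCurve

__all__ = ["PhaseBin", "screen", "bin_phases"]


@dataclass
class PhaseBin:
    site_id: str
    member_ids: list[str]
    representative_id: str
    phase_span_years: float

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member of the bin")


def screen(dates: list[C14Date], max_error: float = 200.0) -> list[C14Date]:
    """Drop dates with lab error > max_error or an insecure archaeological
    association; order preserved, input untouched."""
    return [d for d in dates if d.error <= max_error and d.context_flag == "secure"]


def bin_phases(
    dates: list[C14Date],
    atm: CalCurve,
    mar: CalCurve | None = None,
    h: float = 30.0,
    seed: int = 0,
    medians: dict[str, float] | None = None,
) -> list[PhaseBin]:
    """Partition each site's dates into phases of diameter <= h years.

    Parameters
    ----------
    h : float
        Cut height in years (complete-linkage cophenetic distance); the
        number of bins does not depend on the seed, only the choice of
        representative does.
    medians : dict, optional
        Precomputed median calibrated ages keyed by lab_id (avoids
        recalibration when the caller already has them).
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    if medians is None:
        medians = cal_medians(dates, atm, mar)
    rng = rng_stream(seed, "phasing")
    by_site: dict[str, list[C14Date]] = {}
    for d in dates:
        by_site.setdefault(d.site_id, []).append(d)

    bins: list[PhaseBin] = []
    for site_id in sorted(by_site):
        members = by_site[site_id]
        med = np.array([medians[d.lab_id] for d in members], dtype=float)
        if len(members) == 1:
            labels = np.array([1])
        else:
            Z = linkage(med[:, None], method="complete")
            labels = fcluster(Z, t=h, criterion="distance")
        clusters: dict[int, list[int]] = {}
        for i, lab in enumerate(labels):
            clusters.setdefault(int(lab), []).append(i)
        # deterministic ordering: oldest phase first
        ordered = sorted(clusters.values(), key=lambda idx: -float(med[idx].max()))
        for idx in ordered:
            ids = [members[i].lab_id for i in idx]
            rep = ids[int(rng.integers(len(ids)))]
            span = float(med[idx].max() - med[idx].min())
            bins.append(
                PhaseBin(
                    site_id=site_id,
                    member_ids=ids,
                    representative_id=rep,
                    phase_span_years=span,
                )
            )
    return bins
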