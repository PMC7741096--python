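import numpy as np
import pytest

from paleodem import CalCurve, C14Date, PhaseBin, index_dates, synthetic_curves


@pytest.fixture(scope="session")
def identity_curve():
    """Toy curve mu(t) = t, sigma = 0: calibration is the identity map."""
    grid = np.arange(0.0, 15001.0)
    return CalCurve(grid=grid, mu=grid.copy(), sigma=np.zeros_like(grid), label="identity")


@pytest.fixture(scope="session")
def flat_curve():
    """Toy curve mu = 1000, sigma = 0: every calendar year looks the same."""
    grid = np.arange(0.0, 2001.0)
    return CalCurve(grid=grid, mu=np.full_like(grid, 1000.0), sigma=np.zeros_like(grid), label="flat")


@pytest.fixture(scope="session")
def wiggly_curves():
    """Realistically wiggly synthetic atmospheric + marine curve pair."""
    return synthetic_curves(5500.0, 16000.0)


def make_dates(cras, errors=None, site="S1", site_type="closed", **kw):
    """Build a list of C14Date at given CRAs (same site by default)."""
    if errors is None:
        errors = [20.0] * len(cras)
    return [
        C14Date(
            lab_id=f"{site}-{i}",
            cra=float(c),
            error=float(e),
            site_id=site,
            site_type=site_type,
            **kw,
        )
        for i, (c, e) in enumerate(zip(cras, errors))
    ]


def singleton_bins(dates):
    """One bin per date (used where phase structure is irrelevant)."""
    return [PhaseBin(d.site_id, [d.lab_id], d.lab_id, 0.0) for d in dates]


@pytest.fixture
def dates_factory():
    return make_dates


@pytest.fixture
def bins_factory():
    return singleton_bins
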