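import numpy as np
import pytest

from ringcast.containers import MonthlyClimateSeries, VSLiteParameters
from ringcast.synth import SyntheticSiteSpec, generate_climate


@pytest.fixture(scope="session")
def truth_params():
    return VSLiteParameters()


@pytest.fixture(scope="session")
def default_climate():
    """Moderate mid-latitude site, 1960-2020, seeded."""
    return generate_climate(SyntheticSiteSpec(site_id="fix-default", seed=11))


@pytest.fixture(scope="session")
def long_climate():
    """Same site but starting 1892 so synthetic trees are ~128 years old."""
    return generate_climate(SyntheticSiteSpec(site_id="fix-long", seed=11, years=(1892, 2020)))


@pytest.fixture(scope="session")
def noise_free_climate():
    """Zero interannual noise: every year repeats the seasonal cycle."""
    return generate_climate(
        SyntheticSiteSpec(
            site_id="fix-quiet", seed=0, interannual_sd_temp=0.0, interannual_sd_precip_frac=0.0
        )
    )


def constant_climate(temp_c, precip_mm, n_years=3, latitude=49.0, site_id="const"):
    """Helper: every month of every year identical."""
    return MonthlyClimateSeries(
        site_id=site_id,
        latitude=latitude,
        years=np.arange(2000, 2000 + n_years),
        temp=np.full((n_years, 12), float(temp_c)),
        precip=np.full((n_years, 12), float(precip_mm)),
    )
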