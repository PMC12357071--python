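import numpy as np
import pytest

from trdspat.nbgee import ModelSpec, fit_nb
from trdspat.synthetic_tracts import SyntheticConfig, generate
from trdspat.tract_data import TractRecord


def make_tract(i: int, **kw) -> TractRecord:
    """A valid tract record with overridable fields."""
    defaults = dict(
        tract_id=f"99001{i:06d}",
        county_fips="99001",
        state="SY",
        population=1000,
        retailer_count=2,
        pct_poverty=10.0,
        pct_black=15.0,
        pct_hispanic=5.0,
        pct_asian=2.0,
        pct_white=70.0,
        ruca_code=1,
        appalachia=False,
        centroid=(float(i), 0.0),
    )
    defaults.update(kw)
    return TractRecord(**defaults)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small (10x10) synthetic state with truth, shared across tests."""
    cfg = SyntheticConfig(lattice=(10, 10), seed=42)
    return generate(cfg)


@pytest.fixture(scope="session")
def small_fit(small_synthetic):
    tracts, _, _ = small_synthetic
    return fit_nb(ModelSpec(), tracts)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
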