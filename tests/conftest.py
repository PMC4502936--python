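import numpy as np
import pytest

from wolbprev import ScreenRecord, ScreenTable


def make_record(species="sp", k=0, n=10, **kw):
    defaults = dict(
        study_id="s1",
        species=species,
        family="FamA",
        superfamily="SupA",
        country="C00",
    )
    defaults.update(kw)
    return ScreenRecord(n_sampled=n, n_infected=k, **defaults)


@pytest.fixture
def toy_table():
    """Five species, mixed infection, two countries."""
    recs = [
        make_record("sp1", k=0, n=10, country="C00"),
        make_record("sp1", k=2, n=10, country="C00"),
        make_record("sp2", k=0, n=50, country="C01"),
        make_record("sp3", k=1, n=1, country="C01"),
        make_record("sp4", k=5, n=10, country="C01"),
        make_record("sp5", k=3, n=20, country=None),
    ]
    return ScreenTable(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
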