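import numpy as np
import pytest

import veghealth as vh


@pytest.fixture(scope="session")
def small_config():
    """A small but multi-year record with realistic noise."""
    return vh.SyntheticConfig(n_years=6, n_lat=8, n_lon=8, rng_seed=1234)


@pytest.fixture(scope="session")
def small_fields(small_config):
    return vh.generate_fields(small_config)


@pytest.fixture(scope="session")
def index_chain(small_fields):
    """SMN/SMT → extrema → VCI/TCI/VHI computed once for the session."""
    ndvi, bt, _ = small_fields
    smn = vh.smooth_series(ndvi)
    smt = vh.smooth_series(bt)
    ext_n = vh.climatology_extrema(smn)
    ext_t = vh.climatology_extrema(smt)
    vci = vh.compute_vci(smn, ext_n)
    tci = vh.compute_tci(smt, ext_t)
    vhi = vh.compute_vhi(vci, tci)
    return {"smn": smn, "smt": smt, "ext_n": ext_n, "ext_t": ext_t,
            "vci": vci, "tci": tci, "vhi": vhi}


def make_cube(values, start_year=2000, tag="VHI", mask=None):
    """Build a WeeklyCube from a (T, Y, X) array on a 52-week calendar."""
    values = np.asarray(values, dtype=float)
    nt = values.shape[0]
    n_years = -(-nt // 52)
    year, week = vh.weekly_axis(start_year, n_years)
    return vh.WeeklyCube(values, year[:nt], week[:nt], mask=mask, tag=tag)
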