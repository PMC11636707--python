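import numpy as np
import pandas as pd
import pytest

import bioturbflux as bt


@pytest.fixture(scope="session")
def experiment():
    """A small but complete 72-core mesocosm fixture (shared, read-only)."""
    return bt.make_experiment_fixture(11, n_particles=2000)


@pytest.fixture()
def crank_profile():
    """An exact Crank profile (db = 50 cm²/yr, t = 10 d, N = 0.94)."""
    x = np.arange(0.125, 15.0, 0.25)
    t_yr = 10 / 365
    conc = bt.crank_concentration(x, t_yr, 50.0, 0.94)
    return bt.DepthProfile(x=x, counts=conc, bin_width=0.25, t_yr=t_yr,
                           n_input=0.94, concentration=conc, core_id="exact")


@pytest.fixture()
def flat_metadata():
    """Minimal metadata: two species cores + two controls per site/temp group."""
    rows = []
    k = 0
    for site in ("Uthoern", "Reef"):
        for temp in (15.0, 20.0):
            for species in ("A. marina", "control"):
                k += 1
                rows.append(dict(core_id=f"c{k}", tank=1, species=species,
                                 site=site, temperature_c=temp, afdm_g=2.0,
                                 v_liters=1.0, area_m2=bt.CORE_AREA_M2,
                                 t_days=10.0))
    return pd.DataFrame(rows)
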