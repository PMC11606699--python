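import numpy as np
import pandas as pd
import pytest

from camoccu.simulate import SimulationScenario, gen_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-site synthetic study with events, under dependence (Mod2) truth."""
    sc = SimulationScenario(n_sites=30, structure_label="Mod2")
    return gen_dataset(sc, seed=11)


@pytest.fixture(scope="session")
def study_dataset():
    """A full-scale (77-site) synthetic study without event timestamps."""
    return gen_dataset(seed=3, with_events=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_deployments(n_sites, n_days=30, start="2020-02-01"):
    start = pd.Timestamp(start)
    return pd.DataFrame({
        "station_id": [f"st{i + 1:03d}" for i in range(n_sites)],
        "start_date": [start.date().isoformat()] * n_sites,
        "end_date": [(start + pd.Timedelta(days=n_days - 1)).date().isoformat()] * n_sites,
        "lat": [42.8] * n_sites,
        "lon": [10.3] * n_sites,
    })
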