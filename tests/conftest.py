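import numpy as np
import pandas as pd
import pytest

from heatburden import IndexedTable, synth
from heatburden.tables import VALUE


@pytest.fixture(scope="session")
def mini_bundle():
    return synth.generate_city(synth.mini_template())


@pytest.fixture(scope="session")
def kuopio_bundle():
    return synth.generate_city(synth.kuopio_like_template())


@pytest.fixture()
def rng():
    return np.random.default_rng(20210914)


def random_stock(rng, n_eras=3, year=2010, unit="m2"):
    """A small random single-year building stock for property tests."""
    eras = rng.choice(np.arange(1920, 2010, 10), size=n_eras, replace=False)
    rows = []
    for era in eras:
        for btype in ("a", "b"):
            for state in ("none", "windows", "total_sheath"):
                if rng.random() < 0.25:
                    continue
                rows.append({"Built": int(era), "Building": btype,
                             "Heating": "district", "Renovation": state,
                             VALUE: float(rng.uniform(10, 1e4))})
    if not rows:
        rows.append({"Built": int(eras[0]), "Building": "a",
                     "Heating": "district", "Renovation": "none",
                     VALUE: 100.0})
    return IndexedTable(pd.DataFrame(rows), unit, "stock")
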