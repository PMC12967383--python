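import numpy as np
import pandas as pd
import pytest

from shapeclust.measures import TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20231963)


@pytest.fixture
def random_series(rng):
    """Factory for random rate series on a shared 1963-based axis."""

    def make(k: int = 20, site: str = "s", start: int = 1963) -> TimeSeries:
        years = np.arange(start, start + k)
        return TimeSeries(site=site, years=years, values=rng.uniform(0, 100, k))

    return make


TOY_YEARS = (2000, 2004)  # 5-point toy span


def toy_registry_frame() -> pd.DataFrame:
    """Small registry table: 3 complete sites + 1 incomplete, one subgroup."""
    rows = []
    rates = {
        "alpha": [10.0, 12.0, 14.0, 16.0, 18.0],
        "beta": [50.0, 40.0, 30.0, 20.0, 10.0],
        "gamma": [5.0, 6.0, 5.0, 6.0, 5.0],
    }
    for site, vals in rates.items():
        for i, year in enumerate(range(TOY_YEARS[0], TOY_YEARS[1] + 1)):
            rows.append(
                {"sex": "female", "site": site, "age_group": "40-49",
                 "year": year, "cases": int(vals[i]), "rate": vals[i]}
            )
    # incomplete site: missing the final year
    for i, year in enumerate(range(TOY_YEARS[0], TOY_YEARS[1])):
        rows.append(
            {"sex": "female", "site": "delta", "age_group": "40-49",
             "year": year, "cases": 2, "rate": 2.0}
        )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_registry_csv(tmp_path):
    path = tmp_path / "toy_registry.csv"
    toy_registry_frame().to_csv(path, index=False)
    return path


@pytest.fixture
def toy_config():
    from shapeclust.registry import RegistryConfig

    return RegistryConfig(year_span=TOY_YEARS)
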