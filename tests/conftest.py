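"""Shared fixtures: the packaged registry/population/consumption tables and
the national record set reconstructed from the published DIDs."""

import pandas as pd
import pytest

import pharmprev as pp
from pharmprev.datasets import ddd_registry, national_did, portugal_population


@pytest.fixture(scope="session")
def registry() -> pp.DDDRegistry:
    return ddd_registry()


@pytest.fixture(scope="session")
def population() -> pd.DataFrame:
    return portugal_population()


@pytest.fixture(scope="session")
def published_did() -> pd.DataFrame:
    return national_did()


@pytest.fixture(scope="session")
def national_population(population) -> pd.DataFrame:
    """Single-scope national population (sum over districts per year)."""
    totals = population.groupby("year")["inhabitants"].sum()
    return pd.DataFrame(
        {"region": "Portugal", "year": totals.index, "inhabitants": totals.values}
    )


@pytest.fixture(scope="session")
def national_records(published_did, national_population, registry) -> pd.DataFrame:
    """Dispensing records whose aggregate DIDs equal the published national
    insulin (A10A) and NAD (A10B) class totals for 2018 and 2021."""
    pop = national_population.set_index("year")["inhabitants"]
    lvl3 = published_did[published_did["atc_class"].str.len() == 4]
    frames = [
        pp.records_matching_did(
            "A10AE04" if row.atc_class == "A10A" else "A10BA02",
            row.did,
            int(pop.loc[row.year]),
            "Portugal",
            row.year,
            registry,
        )
        for row in lvl3.itertuples()
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def national_consumption(national_records, registry, national_population) -> pd.DataFrame:
    return pp.aggregate_consumption(
        national_records, registry, national_population, level=3
    )


@pytest.fixture(scope="session")
def base_params() -> dict[int, pp.ModelParams]:
    return {
        2018: pp.ModelParams(undiagnosed_fraction=0.44),
        2021: pp.ModelParams(undiagnosed_fraction=0.357),
    }
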