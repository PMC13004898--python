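import numpy as np
import pandas as pd
import pytest

from prefgxe.elicitation import elicit_responses
from prefgxe.instruments import default_instruments
from prefgxe.simulate import experimental_config, generate


@pytest.fixture(scope="session")
def instruments():
    return default_instruments()


@pytest.fixture(scope="session")
def cohort():
    """A seeded experimental-scale cohort with elicited measures attached."""
    ds = generate(experimental_config(seed=2024))
    el = elicit_responses(ds.data, ds.instruments)
    data = pd.concat(
        [ds.data, el.drop(columns=[c for c in el.columns if c in ds.data.columns])],
        axis=1,
    )
    data["group"] = ds.truth["group_true"].astype(int)
    return ds, data


@pytest.fixture(scope="session")
def golden_fixture():
    """The seed-42, n=400 fixture the frozen reference fits were computed on."""
    ds = generate(experimental_config(seed=42, n=400))
    el = elicit_responses(ds.data, ds.instruments)
    df = pd.DataFrame(
        {
            "pgs": ds.data["pgs"],
            "female": ds.data["female"],
            "group": ds.truth["group_true"].astype(int),
            "crra_lower": el["crra_lower"],
            "crra_upper": el["crra_upper"],
            "la_binary": el["la_binary"],
            "risk_la": el["risk_aversion_la"],
        }
    )
    df["pgs_group"] = df.pgs * df.group
    df["female_group"] = df.female * df.group
    return df
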