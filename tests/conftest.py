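import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import capscore as cs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def compendium() -> pd.DataFrame:
    return cs.load_compendium()


@pytest.fixture(scope="session")
def catalog() -> cs.Catalog:
    return cs.load_default_catalog()


@pytest.fixture(scope="session")
def domain_map() -> cs.DomainMap:
    return cs.default_domain_map()


@pytest.fixture(scope="session")
def synthetic_cohort():
    cfg = cs.SyntheticConfig(n_variants=60, seed=7)
    return cs.generate_cohort(cfg)


def make_score_table(rows: dict[str, tuple[float, float, float]]) -> pd.DataFrame:
    """Raw score table from {'R262W': (polyphen2, sift, provean), ...}."""
    import re

    records = []
    for label, (pp, si, pv) in rows.items():
        ref, pos, alt = re.match(r"([A-Z])(\d+)([A-Z])", label).groups()
        records.append(
            {
                "ref_aa": ref,
                "position": int(pos),
                "alt_aa": alt,
                "polyphen2": pp,
                "sift": si,
                "provean": pv,
            }
        )
    return pd.DataFrame(records, index=list(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20201119)
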