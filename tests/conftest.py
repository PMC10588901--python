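"""Shared fixtures: small hand-built tables and canonical synthetic datasets."""

import numpy as np
import pandas as pd
import pytest

from sevcms import GroupSpec, SyntheticSpec, generate_dataset
from sevcms.datasets import StudyConfig, table_from_dataframe


def make_table(values: dict, groups=None, models=None):
    """Build a ParameterTable from parameter-name -> list-of-values."""
    n = len(next(iter(values.values())))
    df = pd.DataFrame({
        "animal_id": [f"a{i:03d}" for i in range(n)],
        "model": models if models is not None else ["m"] * n,
        "group": groups if groups is not None else ["g"] * n,
    })
    for name, vals in values.items():
        df[name] = vals
    return table_from_dataframe(df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_group_table(rng):
    """40 animals, 6 parameters, treated shifted on the first two."""
    n = 20
    vals = {f"p{j}": np.concatenate([rng.standard_normal(n),
                                     rng.standard_normal(n) + (1.5 if j < 2 else 0)])
            for j in range(6)}
    return make_table(vals, groups=["control"] * n + ["treated"] * n)


@pytest.fixture
def two_group_config():
    return StudyConfig(group_burden_map={"control": 0, "treated": 1}, seed=7)


@pytest.fixture
def planted_spec():
    """Canonical two-class recovery spec: 3 informative of 15, effect 1.5."""
    return SyntheticSpec(
        groups=[GroupSpec("control", 0, 30), GroupSpec("treated", 1, 30)],
        n_parameters=15,
        effects={i: {"treated": 1.5} for i in range(3)},
        seed=0,
    )


@pytest.fixture
def planted_dataset(planted_spec):
    return generate_dataset(planted_spec)
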