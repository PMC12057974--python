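import numpy as np
import pandas as pd
import pytest

from traitnet import RunConfig, SynthConfig, TraitTable, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One complete synthetic study at the default conditions (seed 0)."""
    return generate_study(SynthConfig(), seed=0)


@pytest.fixture()
def small_traits():
    """Tiny hand-made trait table: 2 sites × 3 trees, 3 traits."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(rng.normal(10, 2, size=(6, 3)),
                          columns=["LL", "LN", "PT"])
    sites = pd.Series(["A"] * 3 + ["B"] * 3, name="site")
    cats = {"LL": "morphological", "LN": "stoichiometric", "PT": "anatomical"}
    return TraitTable(values, sites, cats)


@pytest.fixture()
def cfg():
    return RunConfig()
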