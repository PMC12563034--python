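import numpy as np
import pandas as pd
import pytest

from oacsafety import synthetic
from oacsafety.records import COLUMNS


@pytest.fixture(scope="session")
def default_line_list():
    """Default synthetic scenario (two archetypes, published scale ÷100)."""
    config = synthetic.default_config(seed=11)
    records, truth = synthetic.generate(config)
    return config, records, truth


@pytest.fixture()
def tiny_line_list():
    """Hand-written 6-row line list over two drugs and three SOCs."""
    rows = [
        ("C1", "warfarin", "Gastr", "serious", "fatal", "65_85", "F", "IT"),
        ("C1", "warfarin", "Inv", "serious", "recovered", "65_85", "F", "IT"),
        ("C2", "warfarin", "Soc", "non_serious", "unknown", "18_64", "M", "FR"),
        ("C3", "rivaroxaban", "Gastr", "serious", "recovering", "over_85", "M", "DE"),
        ("C4", "rivaroxaban", "Nerv", "serious", "fatal", "over_85", "F", ""),
        ("C5", "rivaroxaban", "Nerv", "non_serious", "recovered", "18_64", "M", "GB"),
    ]
    return pd.DataFrame(rows, columns=list(COLUMNS))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
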