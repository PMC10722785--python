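import warnings
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lifevalues import (ConversionConventionWarning, build_comparison,
                        convert_registry, default_params, default_registry)

DATA = Path(__file__).parent / "data"

warnings.simplefilter("ignore", ConversionConventionWarning)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def converted(registry, params):
    return convert_registry(registry, params)


@pytest.fixture(scope="session")
def comparison_rows(converted):
    return build_comparison(converted)


@pytest.fixture(scope="session")
def printed_tables():
    """Transcription of the published per-country benchmark tables.

    One row per source-table row: adjusted (base-year) value and the printed
    VOLY/VSL/VOQ columns, each as a (lower, upper) pair. ``excluded_cells``
    marks the two cells that are inconsistent with their own row in the
    source (see the note column) and so cannot be reproduced by any single
    coherent conversion chain.
    """
    return pd.read_csv(DATA / "printed_tables.csv", keep_default_na=False)
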