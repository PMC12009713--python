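import numpy as np
import pytest

from tsea import (
    NullBackgroundConfig,
    RankedTaxa,
    generate_fixture_db,
    generate_null_background,
)


@pytest.fixture(scope="session")
def fixture_db():
    """50 synthetic sets (15 small, 20 medium, 15 large) over 300 taxa."""
    return generate_fixture_db(15, 20, 15, universe_size=300, seed=11)


@pytest.fixture(scope="session")
def null_background():
    """One synthetic null background of 300 log2 fold changes."""
    return generate_null_background(NullBackgroundConfig(n_taxa=300, seed=3))


@pytest.fixture()
def small_ranked():
    """Ten taxa with values 1..10 — small enough for exact hand analysis."""
    return RankedTaxa({f"t{i}": float(i) for i in range(1, 11)})
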