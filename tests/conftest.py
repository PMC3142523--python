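import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tripdist import (
    BootstrapForest,
    SyntheticConfig,
    parse_newick,
    simulate_study,
)


@pytest.fixture
def quartet():
    return parse_newick("((a,b),(c,d));")


@pytest.fixture
def conflicting_quartet():
    return parse_newick("((a,c),(b,d));")


@pytest.fixture
def caterpillar():
    return parse_newick("(((a,b),c),d);")


def make_forest(trees, locus="locus"):
    return BootstrapForest(locus=locus, trees=trees)


@pytest.fixture(scope="session")
def small_study():
    """One deterministic synthetic study shared across tests (12 taxa,
    short forests keep it fast)."""
    cfg = SyntheticConfig(n_taxa=12, n_bootstrap=30, n_unpositioned=2, seed=42)
    return simulate_study(cfg)
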