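"""Shared fixtures; instance generators live in :mod:`spiculate.testing`."""

from __future__ import annotations

import numpy as np
import pytest

from spiculate import phylo_io
from spiculate.phylo_io import TimeTree
from spiculate.testing import (  # noqa: F401  (re-exported for the test modules)
    CHARSET,
    make_matrix,
    random_instance,
    random_observations,
    random_rates,
    random_tree,
)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def three_tip_tree() -> TimeTree:
    return phylo_io.parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_tip_tree() -> TimeTree:
    return phylo_io.parse_tree("(((A:3,B:2):4,(C:1,D:5):2):1,E:8);")
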