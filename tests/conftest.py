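"""Shared fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from phylolink.io import Phylogeny


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def cherry():
    return Phylogeny.from_newick("(A:1,B:1);")


@pytest.fixture
def balanced4():
    return Phylogeny.from_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
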