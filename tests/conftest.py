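"""Shared fixtures.

The expensive fixtures (trained networks, experiment runs) are
session-scoped and shared across test modules so the full suite stays
within a laptop-CPU budget. Study conditions live in
:mod:`cellseg.experiments`; the fixtures only cache their results.
"""

from __future__ import annotations

import numpy as np
import pytest

from cellseg import experiments as ex

# re-exported conveniences used by several test modules
DOMAIN_KW = ex.DOMAIN_KW
TINY_NET = ex.desk_net_config(in_channels=1)
domain_scene = ex.domain_scene


@pytest.fixture(scope="session")
def pretrained_domain_a():
    """Tiny network trained on 8 sparse-granular (domain A) scenes."""
    return ex.pretrain_domain_a(seed=0)


@pytest.fixture(scope="session")
def pretrained_no_orphans():
    """Two-channel network whose annotator never labelled orphan nuclei."""
    return ex.pretrain_no_orphan_annotator(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
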