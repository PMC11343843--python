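import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from signaflow import fixtures
from signaflow.io import InputBundle


def world_bundle(seed: int = 1) -> InputBundle:
    world = fixtures.make_toy_world(seed=seed)
    return InputBundle(
        pkn=world.pkn, sources=world.sources,
        regulons_tf=world.regulons_tf, regulons_kin=world.regulons_kin,
        transcriptomics=world.transcriptomics, phospho=world.phospho,
        proteomics=world.proteomics,
        regulatory_sites=fixtures.regulatory_site_db_from_world(world),
        phenotype_edges=world.phenotype_edges, gold=world.gold)


@pytest.fixture(scope="session")
def toy_world():
    return fixtures.make_toy_world(seed=1)


@pytest.fixture(scope="session")
def toy_bundle():
    return world_bundle(seed=1)
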