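from __future__ import annotations

import numpy as np
import pytest

from crossnet.fixtures import (
    gen_metabolic_network,
    gen_module_definition,
    gen_random_scc_spec,
)
from crossnet.kegg_modules import enumerate_alternatives, parse_module_definition


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def random_modules(rng):
    """Parsed random module definitions with planted alternative counts."""
    out = []
    for i in range(20):
        raw, count = gen_module_definition(rng, module_id=f"M{i:05d}")
        definition = parse_module_definition(f"M{i:05d}", raw)
        out.append((definition, enumerate_alternatives(definition), count))
    return out


@pytest.fixture()
def planted_network(rng):
    sizes, edges = gen_random_scc_spec(rng)
    return gen_metabolic_network(sizes, edges, rng=rng)
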