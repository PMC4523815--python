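"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from tagpipe.composition import CommunityDesign, mock_community_design
from tagpipe.synthetic import (
    PlatformErrorModel,
    ReferenceGene,
    generate_reference_set,
)


@pytest.fixture(scope="session")
def mock_design() -> CommunityDesign:
    return mock_community_design()


def rename_refs(refs, design):
    """Map generated organism ids onto a design's organism ids by order."""
    return [
        ReferenceGene(
            organism_id=oid,
            copies=g.copies,
            lineage=g.lineage,
            region_coords=g.region_coords,
        )
        for g, oid in zip(refs, design.organism_ids)
    ]


@pytest.fixture(scope="session")
def refs9(mock_design):
    """Nine organisms, two gene copies each, ids matching the mock design."""
    refs, tree = generate_reference_set(9, 2, seed=11)
    renamed = rename_refs(refs, mock_design)
    for g, r in zip(refs, renamed):
        tree = tree.replace(g.organism_id + "/", r.organism_id.replace(" ", "_") + "/")
    return renamed, tree


@pytest.fixture(scope="session")
def noiseless_model() -> PlatformErrorModel:
    return PlatformErrorModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_read(rng, length=150, q_low=2, q_high=41, n_frac=0.02):
    from tagpipe.readprep import Read

    alphabet = np.array(list("ACGTN"))
    probs = [0.245, 0.245, 0.245, 0.245, 0.02]
    probs = np.array([0.25 - n_frac / 4] * 4 + [n_frac])
    probs = probs / probs.sum()
    bases = "".join(rng.choice(alphabet, size=length, p=probs))
    quals = tuple(int(q) for q in rng.integers(q_low, q_high + 1, size=length))
    return Read(f"rand{rng.integers(1e9)}", bases, quals)
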