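from __future__ import annotations

import numpy as np
import pytest

from vfsage import VFS


def make_vfs(vafs, sample_id="s", source="bulk_reads", depth=1000, age=None):
    """Small helper: a VFS whose counts reproduce the requested VAFs."""
    vafs = np.asarray(vafs, dtype=float)
    if source == "colony_cells":
        mutant = np.round(2 * vafs * depth)
        vaf = 0.5 * mutant / depth
    else:
        mutant = np.round(vafs * depth)
        vaf = mutant / depth
    return VFS(
        sample_id=sample_id,
        variant_ids=np.array([f"v{i}" for i in range(len(vafs))], dtype=object),
        mutant=mutant,
        nonmutant=depth - mutant,
        vaf=vaf,
        source=np.array([source] * len(vafs), dtype=object),
        age=age,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
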