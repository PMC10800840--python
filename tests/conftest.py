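import numpy as np
import pytest

from ecoassembly.io import CommunityTable, PhyloTree, SampleMetadata


@pytest.fixture
def three_leaf_tree() -> PhyloTree:
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_table() -> CommunityTable:
    counts = np.array([
        [5, 3, 1, 1],
        [0, 2, 2, 6],
        [4, 0, 0, 6],
    ], dtype=float)
    return CommunityTable(counts, ["s1", "s2", "s3"], ["A", "B", "C", "D"])


@pytest.fixture
def small_metadata() -> list[SampleMetadata]:
    return [
        SampleMetadata("s1", "surface", 30.2, 125.3, {"pH": 8.1}),
        SampleMetadata("s2", "surface", 30.4, 125.5, {"pH": 8.0}),
        SampleMetadata("s3", "sediment", 30.6, 125.7, {"pH": 7.8}),
    ]
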