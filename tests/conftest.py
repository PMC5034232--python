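import numpy as np
import pytest

from primex.io import parse_newick
from primex.qc import CodonAlignment
from primex.simulate import DEFAULT_SPECIES_TREE_NEWICK


@pytest.fixture
def species_tree():
    return parse_newick(DEFAULT_SPECIES_TREE_NEWICK)


@pytest.fixture
def toy_alignment():
    """Four-taxon, five-codon alignment with a couple of substitutions."""
    return CodonAlignment(
        taxa=["A", "B", "C", "D"],
        sequences=[
            "ATGAAACCCGGGTTT",
            "ATGAAACCCGGGTTT",
            "ATGAAGCCCGGGTTT",
            "ATGAAGCCAGGGTTT",
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
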