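import numpy as np
import pytest

from divsel.io import CodonAlignment, NucAlignment
from divsel.models import CodonModelParams, equal_codon_frequencies
from divsel.trees import PhyloTree


@pytest.fixture
def four_tip_tree() -> PhyloTree:
    return PhyloTree.from_newick("((a:0.1,b:0.2):0.15,(c:0.3,d:0.05):0.1);")


@pytest.fixture
def small_nuc_aln() -> NucAlignment:
    return NucAlignment.from_pairs(
        [("a", "ACGTAC"), ("b", "ACGTAT"), ("c", "ACATAC"), ("d", "GCGTAC")]
    )


@pytest.fixture
def small_codon_aln() -> CodonAlignment:
    rows = [
        ("a", "ATGGCTAAAGGG"),
        ("b", "ATGGCTAAAGGA"),
        ("c", "ATGGCGAAAGGG"),
        ("d", "ATGACTAAAGGG"),
    ]
    return CodonAlignment(
        tuple(n for n, _ in rows), tuple(s for _, s in rows), code_id=1
    )


@pytest.fixture
def codon_params() -> CodonModelParams:
    return CodonModelParams(2.0, equal_codon_frequencies())
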