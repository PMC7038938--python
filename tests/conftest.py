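import numpy as np
import pytest

import ribodeplete as rd


@pytest.fixture(scope="session")
def toy_organism():
    return rd.make_toy_organism(seed=11, n_cds=15)


@pytest.fixture(scope="session")
def toy_library(toy_organism):
    return rd.design_oligo_library(toy_organism.rrnas, organism="toy")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def make_alignment(a_aligned: str, b_aligned: str, score: float = 0.0):
    """Build a PairwiseAlignment directly from gapped strings (test helper)."""
    col_to_a, col_to_b = [], []
    ia = ib = 0
    for ca, cb in zip(a_aligned, b_aligned):
        if ca == "-":
            col_to_a.append(rd.cross_species.GAP)
        else:
            col_to_a.append(ia)
            ia += 1
        if cb == "-":
            col_to_b.append(rd.cross_species.GAP)
        else:
            col_to_b.append(ib)
            ib += 1
    return rd.PairwiseAlignment(a_aligned, b_aligned, col_to_a, col_to_b, score)
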