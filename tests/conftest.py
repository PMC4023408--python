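"""Shared fixtures: small synthetic studies and toy motifs.

Everything is generated programmatically at fixture time; nothing is
read from disk except files the fixtures themselves write to tmp paths.
"""

import numpy as np
import pytest

from motifassoc.motifs import MotifMatrix, make_scoring_matrix
from motifassoc.simulate import SyntheticConfig, nfi_like_motif, simulate_study


SMALL_CONFIG = dict(
    n_genes=400,
    n_chroms=2,
    chrom_length=600_000,
    n_targets_a=40,
    n_targets_b=40,
    n_overlap=15,
    n_peaks=120,
)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study (400 genes, 120 peaks)."""
    return simulate_study(SyntheticConfig(seed=11, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def toy_motif():
    """A sharp 6-bp motif for exhaustive-enumeration tests."""
    counts = np.array(
        [
            [8, 1, 1, 2],
            [1, 9, 1, 1],
            [1, 1, 10, 1],
            [2, 1, 1, 8],
            [6, 2, 2, 2],
            [1, 1, 1, 9],
        ],
        dtype=float,
    )
    return MotifMatrix(id="toy6", counts=counts)


@pytest.fixture(scope="session")
def toy_sm(toy_motif):
    return make_scoring_matrix(toy_motif, pseudocount=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(n, rng, p=None):
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
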