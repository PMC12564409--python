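"""Shared fixtures: Monte-Carlo null tables and guide trees.

The null tables are the expensive shared resources; they are calibrated
once per session.  ``null_10k`` is an exact-length table for the type-I
calibration study; ``null_1m`` is the general-purpose powers-of-two grid
used by every segmentation run on synthetic genomes (contigs up to 2^20).
"""

import numpy as np
import pytest

from segdist.landscape import default_length_grid
from segdist.segmentation import calibrate_null, tapered_sims
from segdist.seqio import Contig, GenomeSequence
from segdist.synthetic import pure_birth_tree


@pytest.fixture(scope="session")
def null_10k():
    return calibrate_null([10_000], k=4, n_sims=2000, seed=101)


@pytest.fixture(scope="session")
def null_1m():
    return calibrate_null(default_length_grid(2**20), k=4,
                          n_sims=tapered_sims(400), seed=7)


@pytest.fixture(scope="session")
def null_small():
    """Cheap table for toy sequences (lengths up to 4096)."""
    return calibrate_null(default_length_grid(4096), k=4, n_sims=500, seed=11)


@pytest.fixture(scope="session")
def tree32():
    return pure_birth_tree(32, seed=3)


@pytest.fixture(scope="session")
def tree128():
    return pure_birth_tree(128, seed=5)


def make_genome(symbols: str, taxon_id: str = "toy", contig_id: str = "c1") -> GenomeSequence:
    return GenomeSequence(taxon_id, [Contig(contig_id, symbols)])


def two_block_sequence(rng: np.random.Generator, gc_left: float, gc_right: float,
                       block: int) -> str:
    """Concatenation of two i.i.d. blocks with the given G+C contents."""
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = []
    for gc in (gc_left, gc_right):
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        out.append(lut[rng.choice(4, size=block, p=p)])
    return np.concatenate(out).tobytes().decode()
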