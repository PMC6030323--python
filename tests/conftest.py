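import numpy as np
import pytest

from perchronos.radmatrix import ConcatenatedAlignment, Locus, LocusMatrix


def make_alignment(rows, individuals=None, locus_id="L1") -> ConcatenatedAlignment:
    """Alignment from a list of equal-length strings (one per individual)."""
    if individuals is None:
        individuals = [f"t{i}" for i in range(len(rows))]
    mat = np.frombuffer("".join(rows).encode("ascii"), dtype="S1")
    mat = mat.reshape(len(rows), len(rows[0])).copy()
    return ConcatenatedAlignment(list(individuals), mat,
                                 {locus_id: (0, len(rows[0]))})


def make_locus_matrix(loci_spec, individuals):
    """loci_spec: dict locus_id -> dict individual -> sequence."""
    loci = [Locus(lid, len(next(iter(seqs.values()))), dict(seqs))
            for lid, seqs in loci_spec.items()]
    return LocusMatrix(loci, list(individuals))


@pytest.fixture
def aln_factory():
    return make_alignment


@pytest.fixture
def matrix_factory():
    return make_locus_matrix
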