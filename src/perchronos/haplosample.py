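"""Repeated random haplotype sampling (RRHS).

Diploid consensus sequences carry two-base IUPAC codes at heterozygous sites.
RRHS pseudo-phases such data by independently resolving every heterozygous
site to one of its two bases with probability 1/2, producing a replicate
alignment over {A,C,G,T,N,-}; repeating this many times propagates phasing
uncertainty into downstream tree inference.  ``N`` is unknown data, not a
four-way heterozygote, and is left untouched.

Per-replicate seeds are derived from a counter-based scheme: replicate ``i``
uses ``numpy.random.default_rng([master_seed, i])``, so any single replicate
is reproducible without generating its predecessors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .radmatrix import HET_CODES, ConcatenatedAlignment


@dataclass
class RRHSReplicate:
    index: int
    seed: tuple[int, int]
    alignment: ConcatenatedAlignment


_HET_BYTES = {code.encode(): (pair[0].encode(), pair[1].encode())
              for code, pair in HET_CODES.items()}


def _resolve(matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = matrix.copy()
    for code, (b0, b1) in _HET_BYTES.items():
        mask = matrix == code
        k = int(mask.sum())
        if k == 0:
            continue
        pick = rng.integers(0, 2, size=k)
        out[mask] = np.where(pick == 0, b0, b1)
    return out


def rrhs_resolve(a: ConcatenatedAlignment, seed, index: int = 0) -> RRHSReplicate:
    """Resolve every heterozygous site to one base, deterministically per seed."""
    rng = np.random.default_rng(seed)
    resolved = ConcatenatedAlignment(
        list(a.individuals), _resolve(a.matrix, rng), dict(a.partitions),
        dict(a.metadata),
    )
    seed_t = tuple(seed) if isinstance(seed, (list, tuple)) else (seed,)
    return RRHSReplicate(index, seed_t, resolved)


def rrhs_replicates(a: ConcatenatedAlignment, n: int,
                    master_seed: int) -> list[RRHSReplicate]:
    """Generate ``n`` independently seeded RRHS replicate alignments."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [rrhs_resolve(a, [master_seed, i], index=i) for i in range(n)]


def iter_rrhs(a: ConcatenatedAlignment, n: int, master_seed: int):
    """Lazy variant of :func:`rrhs_replicates` for large replicate counts."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for i in range(n):
        yield rrhs_resolve(a, [master_seed, i], index=i)
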