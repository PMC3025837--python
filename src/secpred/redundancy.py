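"""Pairwise-identity culling of sequence sets.

Training and test sets for sequence classifiers must not share near-identical
sequences, or cross-validation estimates leak.  This module reduces a set so
that no retained pair exceeds an identity threshold (default 25%), the role a
PSI-BLAST-profile-based culling server plays at database scale.

The identity measure is an injection point: any callable
``(SequenceRecord, SequenceRecord) -> float`` in [0, 1] may be supplied.  The
default is deterministic global alignment (BLOSUM62, affine gaps -11/-1) with
identity defined as matched columns over alignment length.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .sequences import SequenceRecord

IdentityFn = Callable[[SequenceRecord, SequenceRecord], float]


@lru_cache(maxsize=1)
def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Global-alignment identity fraction in [0, 1].

    identity = matched columns / alignment length (gap columns included in the
    denominator), so unrelated sequences score near 0 and a sequence scores
    exactly 1.0 against itself.  Symmetric by construction of the optimal
    global alignment score; ties in the alignment path do not affect the
    count of identities of the first reported alignment in practice, and the
    measure is only used against a threshold.
    """
    if a.residues == b.residues:
        return 1.0
    aln = _default_aligner().align(a.residues, b.residues)[0]
    counts = aln.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / total if total else 0.0


@dataclass
class IdentityMatrix:
    """Symmetric all-against-all identity fractions for a set of records."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("identity matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("identity matrix diagonal must be 1.0")
        self.values = v


def identity_matrix(
    records: Sequence[SequenceRecord], identity_fn: IdentityFn = pairwise_identity
) -> IdentityMatrix:
    """Compute the all-against-all identity matrix (upper triangle mirrored)."""
    n = len(records)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = identity_fn(records[i], records[j])
    return IdentityMatrix(ids=[r.id for r in records], values=values)


def cull(
    records: Sequence[SequenceRecord],
    threshold: float = 0.25,
    identity_fn: IdentityFn = pairwise_identity,
) -> list[SequenceRecord]:
    """Greedily reduce ``records`` so no retained pair has identity > threshold.

    Candidates are visited by descending length (ties broken by id) and a
    record is accepted iff its identity to every already-accepted record is
    <= ``threshold``.  Longest-first favours keeping the most informative
    sequences and makes the procedure deterministic for a fixed input set.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    accepted: list[SequenceRecord] = []
    for candidate in ordered:
        if all(identity_fn(candidate, kept) <= threshold for kept in accepted):
            accepted.append(candidate)
    original_order = {r.id: i for i, r in enumerate(records)}
    accepted.sort(key=lambda r: original_order[r.id])
    return accepted
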