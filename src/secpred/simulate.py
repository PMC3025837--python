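"""Synthetic two-class sequence sets with controllable, plantable signal.

The generator emulates the statistical structure the classifier exploits in
real secretomes, without any database dependency: the two classes differ in
amino-acid composition (strength ``separation``), optionally in first-order
residue adjacency (strength ``order_signal``), and each sequence can be
paired with a consistent synthetic conservation profile.  Setting both
strengths to zero makes the classes exchangeable, which is the null model
the selection machinery is validated against.

Composition signal: the positive class moves ``separation`` of probability
mass onto a designated residue subset, taken uniformly from the remaining
residues, so the total-variation distance between class compositions grows
linearly with ``separation``.

Adjacency signal: residues are drawn from a first-order Markov chain whose
rows start at the class composition; the positive class adds ``order_signal``
to self-transitions (favouring residue repeats) and the negative class to
transitions to the next residue in alphabetical order, rows renormalised.

All randomness flows from one :func:`numpy.random.default_rng` stream seeded
by ``FixtureSpec.seed``, so output is reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequences import ALPHABET, NCBI_ORDER, PSSMProfile, SequenceRecord, write_pssm

#: Residues receiving the positive class's extra composition mass.
SIGNAL_RESIDUES = ("A", "E", "K", "L", "S")

_NCBI_INDEX = {a: i for i, a in enumerate(NCBI_ORDER)}


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for one synthetic two-class sequence set.

    separation
        Total probability mass shifted onto :data:`SIGNAL_RESIDUES` in the
        positive class; 0 removes the composition signal.
    order_signal
        Per-transition bias distinguishing the classes' dipeptide structure;
        0 makes both classes zeroth-order.
    """

    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (50, 150)
    separation: float = 0.2
    order_signal: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one sequence per class")
        lo, hi = self.length_range
        if not (50 <= lo <= hi <= 10000):
            raise ValueError("length_range must lie within [50, 10000]")
        if self.separation < 0 or self.order_signal < 0:
            raise ValueError("separation and order_signal must be >= 0")


def class_compositions(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """(positive, negative) residue compositions in alphabetical order."""
    base = np.full(20, 0.05)
    pos = base.copy()
    signal_idx = [ALPHABET.index(a) for a in SIGNAL_RESIDUES]
    other_idx = [i for i in range(20) if i not in signal_idx]
    pos[signal_idx] += spec.separation / len(signal_idx)
    pos[other_idx] -= spec.separation / len(other_idx)
    if np.any(pos < 0):
        raise ValueError(
            f"separation={spec.separation} drives a residue probability negative"
        )
    return pos, base


def _transition_matrix(
    comp: np.ndarray, order_signal: float, positive: bool
) -> np.ndarray:
    T = np.tile(comp, (20, 1))
    for a in range(20):
        target = a if positive else (a + 1) % 20
        T[a, target] += order_signal
    T /= T.sum(axis=1, keepdims=True)
    if np.any(T < 0):
        raise ValueError("order_signal drives a transition probability negative")
    return T


def _draw_sequence(
    rng: np.random.Generator, length: int, comp: np.ndarray, T: np.ndarray | None
) -> str:
    if T is None:
        idx = rng.choice(20, size=length, p=comp)
    else:
        idx = np.empty(length, dtype=int)
        idx[0] = rng.choice(20, p=comp)
        for i in range(1, length):
            idx[i] = rng.choice(20, p=T[idx[i - 1]])
    return "".join(ALPHABET[i] for i in idx)


def generate(spec: FixtureSpec) -> tuple[list[SequenceRecord], list[int]]:
    """Generate a labelled record list: positives first (+1), then negatives (-1)."""
    rng = np.random.default_rng(spec.seed)
    pos_comp, neg_comp = class_compositions(spec)
    use_markov = spec.order_signal > 0
    T_pos = _transition_matrix(pos_comp, spec.order_signal, True) if use_markov else None
    T_neg = _transition_matrix(neg_comp, spec.order_signal, False) if use_markov else None
    lo, hi = spec.length_range
    records: list[SequenceRecord] = []
    labels: list[int] = []
    for klass, n, comp, T in (
        ("pos", spec.n_pos, pos_comp, T_pos),
        ("neg", spec.n_neg, neg_comp, T_neg),
    ):
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            residues = _draw_sequence(rng, length, comp, T)
            records.append(SequenceRecord(id=f"{klass}_{i + 1:04d}", residues=residues))
            labels.append(1 if klass == "pos" else -1)
    return records, labels


def generate_pssm(
    record: SequenceRecord, noise: float = 1.0, seed: int = 0
) -> PSSMProfile:
    """Sequence-faithful synthetic profile: +7 at each position's own residue
    column, -2 elsewhere, plus integer-rounded Gaussian noise of scale ``noise``.
    """
    rng = np.random.default_rng(seed)
    L = len(record)
    scores = np.full((L, 20), -2.0)
    for i, residue in enumerate(record.residues):
        scores[i, _NCBI_INDEX[residue]] = 7.0
    if noise > 0:
        scores += np.round(rng.normal(0.0, noise, size=(L, 20)))
    return PSSMProfile(
        sequence_id=record.id, scores=scores, residues=record.residues
    )


def generate_profiles(
    records: Sequence[SequenceRecord], noise: float = 1.0, seed: int = 0
) -> dict[str, PSSMProfile]:
    """One profile per record, each on its own derived sub-seed."""
    return {
        r.id: generate_pssm(r, noise=noise, seed=(seed * 7919 + i) % (2**31 - 1))
        for i, r in enumerate(records)
    }


def write_profiles(
    profiles: dict[str, PSSMProfile], directory: str | Path
) -> list[Path]:
    """Write each profile as ``<id>.pssm`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for rid in sorted(profiles):
        path = directory / f"{rid}.pssm"
        write_pssm(profiles[rid], path)
        paths.append(path)
    return paths
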