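"""Fixed-length feature encodings of protein sequences.

Variable-length sequences carry no vector-space structure ("the sequence
metric problem"), so kernel classifiers need them mapped to fixed-length
vectors first.  Four encodings are provided:

``frequencies`` (20)
    Amino-acid composition: count of each residue divided by sequence length.
``dipeptides`` (400)
    Overlapping adjacent-pair composition: counts of each ordered pair
    divided by L-1; captures local order as well as composition.
``factors`` (100)
    Composition weighted by the five multivariate physicochemical factors of
    Atchley et al. (polarity, secondary-structure propensity, molecular
    volume, relative composition/codon diversity, electrostatic charge):
    entry (a, f) = composition(a) * factor_f(a), a 20 x 5 outer product
    flattened row-major.
``pssm`` (400)
    An L x 20 position-specific scoring matrix is collapsed to 20 x 20 by
    summing profile rows grouped by the residue type at each position
    (Jones-style), divided by sequence length, then squashed into (0, 1)
    with the logistic sigmoid.

Composition and dipeptide axes use alphabetical residue order
(:data:`~secpred.sequences.ALPHABET`); the PSSM block uses NCBI column order
on both axes.  Any non-empty subset of the four blocks can be concatenated
(15 combinations) and serialised in LIBSVM sparse format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequences import ALPHABET, NCBI_ORDER, PSSMProfile, SequenceRecord

#: Canonical block order for concatenation.
CANONICAL_FEATURES = ("frequencies", "dipeptides", "factors", "pssm")

#: Dimensionality of each encoder block.
FEATURE_DIMS = {"frequencies": 20, "dipeptides": 400, "factors": 100, "pssm": 400}

_ALPHA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
_NCBI_INDEX = {a: i for i, a in enumerate(NCBI_ORDER)}

# Atchley et al. multivariate factor scores, one row per residue (alphabetical),
# columns: I polarity, II secondary structure, III molecular size/volume,
# IV relative amino-acid composition, V electrostatic charge.
ATCHLEY_FACTORS = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}


def factor_table(table: Mapping[str, Sequence[float]] = ATCHLEY_FACTORS) -> np.ndarray:
    """Return the 20 x 5 factor matrix, rows in alphabetical residue order."""
    missing = set(ALPHABET) - set(table)
    if missing:
        raise ValueError(f"factor table missing residues {sorted(missing)}")
    mat = np.array([table[a] for a in ALPHABET], dtype=float)
    if mat.shape != (20, 5):
        raise ValueError(f"factor table must be 20x5, got {mat.shape}")
    return mat


@dataclass
class FeatureVector:
    """Fixed-length numeric encoding of one sequence with block provenance.

    ``schema`` records which encoders produced which slice, as ordered
    (name, dimension) pairs whose dimensions sum to ``len(values)``.
    """

    sequence_id: str
    values: np.ndarray
    schema: tuple[tuple[str, int], ...]
    label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        total = sum(d for _, d in self.schema)
        if total != self.values.size:
            raise ValueError(
                f"schema dims sum to {total} but vector has {self.values.size}"
            )

    @property
    def dim(self) -> int:
        return self.values.size


def encode_composition(record: SequenceRecord) -> FeatureVector:
    """20-d amino-acid composition: count(a) / L, alphabetical order."""
    counts = np.zeros(20)
    for residue in record.residues:
        counts[_ALPHA_INDEX[residue]] += 1
    return FeatureVector(
        sequence_id=record.id,
        values=counts / len(record),
        schema=(("frequencies", 20),),
    )


def encode_dipeptide(record: SequenceRecord) -> FeatureVector:
    """400-d overlapping dipeptide composition: count(ab) / (L-1), row-major."""
    if len(record) < 2:
        raise ValueError(f"record {record.id!r}: dipeptides need length >= 2")
    counts = np.zeros((20, 20))
    seq = record.residues
    for a, b in zip(seq, seq[1:]):
        counts[_ALPHA_INDEX[a], _ALPHA_INDEX[b]] += 1
    return FeatureVector(
        sequence_id=record.id,
        values=counts.ravel() / (len(record) - 1),
        schema=(("dipeptides", 400),),
    )


def encode_factors(
    record: SequenceRecord, table: Mapping[str, Sequence[float]] | None = None
) -> FeatureVector:
    """100-d physicochemical encoding: composition ⊗ factor table.

    Entry (a, f) = composition(a) * factor_f(a), flattened row-major over the
    alphabetical residue axis then the five factors, so a residue absent from
    the sequence contributes five exact zeros.
    """
    mat = factor_table(table if table is not None else ATCHLEY_FACTORS)
    comp = encode_composition(record).values
    values = (comp[:, None] * mat).ravel()
    return FeatureVector(
        sequence_id=record.id, values=values, schema=(("factors", 100),)
    )


def encode_pssm(record: SequenceRecord, profile: PSSMProfile) -> FeatureVector:
    """400-d PSSM encoding: residue-type-grouped row sums, / L, then sigmoid.

    For residue type ``a`` and score column ``j``,
    ``S[a, j] = sum_i { scores[i, j] : residues[i] == a }``; each entry is
    divided by the sequence length and mapped through ``1 / (1 + exp(-x))``.
    Both axes follow NCBI PSSM column order.  Residue types absent from the
    sequence give raw 0, hence sigmoid 0.5.
    """
    if profile.scores.shape[0] != len(record):
        raise ValueError(
            f"record {record.id!r}: profile has {profile.scores.shape[0]} rows "
            f"for a {len(record)}-residue sequence"
        )
    if profile.residues != record.residues:
        raise ValueError(
            f"record {record.id!r}: profile residue column disagrees with sequence"
        )
    collapsed = np.zeros((20, 20))
    for i, residue in enumerate(record.residues):
        collapsed[_NCBI_INDEX[residue]] += profile.scores[i]
    collapsed /= len(record)
    values = 1.0 / (1.0 + np.exp(-collapsed.ravel()))
    return FeatureVector(
        sequence_id=record.id, values=values, schema=(("pssm", 400),)
    )


def encode_record(
    record: SequenceRecord,
    features: Sequence[str] = CANONICAL_FEATURES,
    profile: PSSMProfile | None = None,
    table: Mapping[str, Sequence[float]] | None = None,
) -> dict[str, FeatureVector]:
    """Encode one record with each requested encoder, keyed by block name."""
    out: dict[str, FeatureVector] = {}
    for name in features:
        if name == "frequencies":
            out[name] = encode_composition(record)
        elif name == "dipeptides":
            out[name] = encode_dipeptide(record)
        elif name == "factors":
            out[name] = encode_factors(record, table)
        elif name == "pssm":
            if profile is None:
                raise ValueError(f"record {record.id!r}: pssm requested but no profile")
            out[name] = encode_pssm(record, profile)
        else:
            raise ValueError(f"unknown feature block {name!r}")
    return out


def combine(
    vectors: Mapping[str, FeatureVector] | Sequence[FeatureVector],
    mask: Iterable[str],
) -> FeatureVector:
    """Concatenate selected blocks in canonical order.

    ``mask`` selects a non-empty subset of
    {frequencies, dipeptides, factors, pssm}; the result's schema records the
    block boundaries.  All vectors must belong to the same sequence.
    """
    if not isinstance(vectors, Mapping):
        vectors = {v.schema[0][0]: v for v in vectors}
    mask = set(mask)
    unknown = mask - set(CANONICAL_FEATURES)
    if unknown:
        raise ValueError(f"unknown feature blocks {sorted(unknown)}")
    if not mask:
        raise ValueError("empty feature mask")
    missing = mask - set(vectors)
    if missing:
        raise ValueError(f"feature blocks not provided: {sorted(missing)}")
    selected = [vectors[name] for name in CANONICAL_FEATURES if name in mask]
    ids = {v.sequence_id for v in selected}
    if len(ids) != 1:
        raise ValueError(f"vectors from multiple sequences: {sorted(ids)}")
    labels = {v.label for v in selected if v.label is not None}
    return FeatureVector(
        sequence_id=selected[0].sequence_id,
        values=np.concatenate([v.values for v in selected]),
        schema=tuple(pair for v in selected for pair in v.schema),
        label=labels.pop() if len(labels) == 1 else None,
    )


# ---------------------------------------------------------------------------
# LIBSVM sparse format
# ---------------------------------------------------------------------------

def write_libsvm(
    vectors: Sequence[FeatureVector],
    path: str | Path,
    float_format: str = "{:.6f}",
) -> None:
    """Write labelled vectors as LIBSVM sparse lines.

    One line per vector: ``<label> <index>:<value> ...`` with ascending
    1-based indices and exact zeros omitted.  Output is byte-deterministic
    for a fixed input and float format (default six decimal places).
    """
    lines = []
    for v in vectors:
        if v.label is None:
            raise ValueError(f"vector for {v.sequence_id!r} has no label")
        label = "+1" if v.label > 0 else "-1"
        pairs = [
            f"{i + 1}:{float_format.format(x)}"
            for i, x in enumerate(v.values)
            if x != 0.0
        ]
        lines.append(" ".join([label, *pairs]).rstrip())
    Path(path).write_text("\n".join(lines) + "\n")


def read_libsvm(path: str | Path, dim: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Parse LIBSVM sparse lines back into a dense (X, y) pair."""
    labels: list[int] = []
    rows: list[dict[int, float]] = []
    max_index = 0
    for line in Path(path).read_text().splitlines():
        tokens = line.split()
        if not tokens:
            continue
        labels.append(int(tokens[0]))
        row: dict[int, float] = {}
        for pair in tokens[1:]:
            idx, val = pair.split(":")
            row[int(idx)] = float(val)
            max_index = max(max_index, int(idx))
        rows.append(row)
    dim = dim or max_index
    X = np.zeros((len(rows), dim))
    for i, row in enumerate(rows):
        for idx, val in row.items():
            X[i, idx - 1] = val
    return X, np.array(labels, dtype=int)
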