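"""Sequence and profile I/O plus dataset-curation filters.

Protein sequences enter as FASTA, per-sequence conservation profiles as
NCBI BLAST ASCII position-specific scoring matrices (the one-row-per-position
dialect with 20 log-odds columns), and optional curation annotations as a
simple tab-separated sidecar table (id, keywords, signal-region end).

The curation filters implement the screening rules used to assemble
training sets for secretion classifiers: length bounds (50–10 000 residues),
exclusion of dubiously annotated entries ("fragment", "putative", ...), and
removal of the N-terminal signal/translocation region from positive examples
so that the classifier cannot key on the signal peptide itself.

Coordinates are 1-based inclusive, following the SwissProt feature-table
convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord as _BioRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: The 20 standard residues in alphabetical order (composition/dipeptide axis).
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Residue order of NCBI PSSM score columns.
NCBI_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Annotation words that disqualify a record from training sets.
DEFAULT_EXCLUSION_WORDS = (
    "fragment",
    "probable",
    "probably",
    "potential",
    "hypothetical",
    "putative",
    "maybe",
    "likely",
)

_ALPHABET_SET = frozenset(ALPHABET)

InvalidPolicy = Literal["reject", "error"]


@dataclass
class SequenceRecord:
    """One validated protein sequence plus optional curation annotations.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header up to first whitespace).
    residues : str
        Upper-case sequence over the 20 standard amino-acid letters.
    keywords : tuple of str, optional
        Annotation words/phrases read from the sidecar table.
    signal_end : int, optional
        1-based position of the last residue of the annotated
        signal/translocation region; must satisfy ``1 <= signal_end < len``.
    """

    id: str
    residues: str
    keywords: tuple[str, ...] = field(default_factory=tuple)
    signal_end: int | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - _ALPHABET_SET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-standard residues {sorted(bad)}"
            )
        if self.signal_end is not None:
            if not 1 <= self.signal_end < len(self.residues):
                raise ValueError(
                    f"record {self.id!r}: signal_end={self.signal_end} outside "
                    f"[1, {len(self.residues) - 1}]"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PSSMProfile:
    """L x 20 log-odds profile tied to one sequence.

    ``scores[i, j]`` is the log-odds score of residue ``NCBI_ORDER[j]`` at
    position ``i`` (0-based).  The per-position residue letters are retained
    so the profile can be cross-checked against its sequence at encoding time.
    """

    sequence_id: str
    scores: np.ndarray
    residues: str
    column_order: str = NCBI_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"profile {self.sequence_id!r}: scores must be L x 20, "
                f"got {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.residues):
            raise ValueError(
                f"profile {self.sequence_id!r}: {self.scores.shape[0]} rows for "
                f"{len(self.residues)} residues"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, invalid: InvalidPolicy = "reject") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Residues are upper-cased.  Entries containing characters outside the
    20-letter alphabet (B, J, O, U, X, Z, ``*``, gap characters, ...) are
    handled per ``invalid``: ``"reject"`` (default) drops the entry with a
    logged warning, ``"error"`` raises.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file contains no FASTA entries at all.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    n_entries = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_entries += 1
        residues = str(entry.seq).upper().replace(" ", "")
        try:
            records.append(SequenceRecord(id=entry.id, residues=residues))
        except ValueError as exc:
            if invalid == "error":
                raise
            logger.warning("skipping %s: %s", entry.id, exc)
    if n_entries == 0:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (stable formatting for reproducibility)."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# ASCII PSSM
# ---------------------------------------------------------------------------

def read_pssm(path: str | Path, sequence_id: str | None = None) -> PSSMProfile:
    """Parse an NCBI BLAST ASCII PSSM (one row per position, 20 log-odds columns).

    Header lines are skipped up to the column-letter line.  Each data row is
    ``index residue s1 ... s20 [trailing columns ignored]``; trailing weighted
    percentages / information columns of the full blastpgp output are tolerated.

    Raises
    ------
    ValueError
        If a data row does not provide 20 numeric score fields (the error
        message names the offending line number).
    """
    path = Path(path)
    rows: list[list[float]] = []
    residues: list[str] = []
    in_body = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                if in_body and rows:
                    break  # blank line ends the matrix body
                continue
            if not in_body:
                # the column-header line lists residue letters (20 or 40 of them)
                if len(tokens) >= 20 and all(t in _ALPHABET_SET for t in tokens):
                    in_body = True
                continue
            if not tokens[0].isdigit():
                break  # footer (lambda/K statistics)
            if len(tokens) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected index, residue and 20 scores, "
                    f"got {len(tokens)} fields"
                )
            try:
                scores = [float(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score field: {exc}")
            residues.append(tokens[1].upper())
            rows.append(scores)
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    return PSSMProfile(
        sequence_id=sequence_id or path.stem,
        scores=np.array(rows, dtype=float),
        residues="".join(residues),
    )


def write_pssm(profile: PSSMProfile, path: str | Path) -> None:
    """Write a profile in the ASCII PSSM dialect that :func:`read_pssm` reads."""
    with open(path, "w") as fh:
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n\n"
        )
        fh.write("     " + "".join(f"{a:>4}" for a in profile.column_order) + "\n")
        for i, (res, row) in enumerate(zip(profile.residues, profile.scores), start=1):
            cells = "".join(f"{int(round(v)):>4d}" for v in row)
            fh.write(f"{i:>4} {res}{cells}\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# Annotation sidecar
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[str, tuple[tuple[str, ...], int | None]]:
    """Read the tab-separated annotation sidecar: ``id<TAB>keywords<TAB>signal_end``.

    Keywords are ``;``- or ``,``-separated; the signal_end column may be empty.
    Lines starting with ``#`` are comments.
    """
    table: dict[str, tuple[tuple[str, ...], int | None]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rid = parts[0].strip()
            kw: tuple[str, ...] = ()
            if len(parts) > 1 and parts[1].strip():
                kw = tuple(
                    w.strip() for w in re.split(r"[;,]", parts[1]) if w.strip()
                )
            signal_end = None
            if len(parts) > 2 and parts[2].strip():
                signal_end = int(parts[2])
            table[rid] = (kw, signal_end)
    return table


def attach_annotations(
    records: Sequence[SequenceRecord],
    annotations: dict[str, tuple[tuple[str, ...], int | None]],
) -> list[SequenceRecord]:
    """Return copies of ``records`` with keywords/signal_end from the sidecar."""
    out = []
    for r in records:
        if r.id in annotations:
            kw, signal_end = annotations[r.id]
            out.append(replace(r, keywords=kw, signal_end=signal_end))
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Curation filters
# ---------------------------------------------------------------------------

def length_filter(
    records: Iterable[SequenceRecord], min_len: int = 50, max_len: int = 10000
) -> list[SequenceRecord]:
    """Keep records with ``min_len <= length <= max_len`` (inclusive bounds)."""
    if min_len < 1 or max_len < min_len:
        raise ValueError(f"invalid length bounds [{min_len}, {max_len}]")
    return [r for r in records if min_len <= len(r) <= max_len]


def annotation_filter(
    records: Iterable[SequenceRecord],
    exclusion_words: Sequence[str] = DEFAULT_EXCLUSION_WORDS,
) -> list[SequenceRecord]:
    """Drop records whose keywords contain any exclusion word.

    Matching is case-insensitive and whole-word: the keyword phrase
    "putative kinase" is excluded, "reputation" is not.
    """
    if not exclusion_words:
        return list(records)
    pattern = re.compile(
        r"\b(?:" + "|".join(re.escape(w) for w in exclusion_words) + r")\b",
        re.IGNORECASE,
    )
    return [
        r for r in records if not any(pattern.search(k) for k in r.keywords)
    ]


def strip_signal_region(record: SequenceRecord) -> SequenceRecord:
    """Remove residues 1..signal_end (1-based, inclusive) from a record.

    Records without an annotated ``signal_end`` are returned unchanged, so the
    function can be mapped over a mixed batch.  Raises if removal would leave
    an empty sequence (``signal_end >= length`` is rejected at construction,
    but the check is repeated here for defence).
    """
    if record.signal_end is None:
        return record
    if record.signal_end >= len(record):
        raise ValueError(
            f"record {record.id!r}: signal_end={record.signal_end} leaves no residues"
        )
    return SequenceRecord(
        id=record.id,
        residues=record.residues[record.signal_end:],
        keywords=record.keywords,
        signal_end=None,
    )


def strip_signal_regions(records: Iterable[SequenceRecord]) -> list[SequenceRecord]:
    """Batch form of :func:`strip_signal_region`."""
    return [strip_signal_region(r) for r in records]
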