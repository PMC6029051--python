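"""Peptide records, validation, and labeled dataset assembly.

Every downstream encoder assumes the 20-letter amino-acid alphabet, so
validation is strict: records containing ambiguity or non-canonical codes
(B, J, O, U, X, Z) are rejected with an error naming the record rather
than silently skipped or translated.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical residue alphabet, alphabetical by one-letter code. This ordering
#: fixes the layout of every feature vector in the package.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_ALPHABET_SET = frozenset(ALPHABET)

EPITOPE = "epitope"
NON_EPITOPE = "non_epitope"
UNLABELED = "unlabeled"
LABELS = (EPITOPE, NON_EPITOPE, UNLABELED)

#: Inclusive peptide length bounds used throughout: 3 to 30 residues.
DEFAULT_LENGTH_BOUNDS = (3, 30)


class PeptideValidationError(ValueError):
    """A sequence or record violates the peptide contract."""


class DatasetError(ValueError):
    """A labeled dataset cannot be assembled as requested."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with an optional class label.

    The sequence is upper-cased on construction and must consist solely of
    the 20 canonical residues.
    """

    id: str
    sequence: str
    label: str = UNLABELED

    def __post_init__(self) -> None:
        if not self.id:
            raise PeptideValidationError("peptide id must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise PeptideValidationError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(seq) - _ALPHABET_SET)
        if bad:
            raise PeptideValidationError(
                f"record {self.id!r}: non-canonical residue(s) "
                f"{', '.join(repr(b) for b in bad)}"
            )
        if self.label not in LABELS:
            raise PeptideValidationError(
                f"record {self.id!r}: unknown label {self.label!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: str) -> "Peptide":
        return replace(self, label=label)


@dataclass(frozen=True)
class PeptideDataset:
    """A two-class peptide dataset with inclusive length bounds.

    Invariants: every sequence length lies inside ``length_bounds`` and no
    sequence string is duplicated within a class. A sequence may appear in
    both classes (see :func:`build_dataset` for the policy).
    """

    positives: tuple
    negatives: tuple
    length_bounds: tuple = DEFAULT_LENGTH_BOUNDS

    def __post_init__(self) -> None:
        lo, hi = self.length_bounds
        object.__setattr__(self, "positives", tuple(self.positives))
        object.__setattr__(self, "negatives", tuple(self.negatives))
        for name, group in (("positive", self.positives), ("negative", self.negatives)):
            seen = set()
            for p in group:
                if not lo <= len(p) <= hi:
                    raise DatasetError(
                        f"{name} peptide {p.id!r} has length {len(p)} outside "
                        f"[{lo}, {hi}]"
                    )
                if p.sequence in seen:
                    raise DatasetError(
                        f"duplicate {name} sequence {p.sequence!r} ({p.id!r})"
                    )
                seen.add(p.sequence)

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    def all_peptides(self) -> list:
        return list(self.positives) + list(self.negatives)

    def to_frame(self) -> pd.DataFrame:
        """Dataset manifest as a DataFrame (id, sequence, label, length)."""
        rows = [
            (p.id, p.sequence, p.label, len(p)) for p in self.all_peptides()
        ]
        return pd.DataFrame(rows, columns=["id", "sequence", "label", "length"])

    def write_manifest(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def length_histogram(self) -> Counter:
        return Counter(len(p) for p in self.all_peptides())


def read_fasta(path, label: str = UNLABELED) -> list:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    The record id is the first whitespace-delimited token of the header.
    Ids must be unique within the file; sequences are validated against the
    canonical alphabet.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FASTA file: {path}")
    peptides = []
    seen_ids = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen_ids:
            raise PeptideValidationError(
                f"{path}: duplicate record id {rec.id!r}"
            )
        seen_ids.add(rec.id)
        peptides.append(Peptide(rec.id, str(rec.seq), label))
    return peptides


def write_fasta(peptides: Iterable[Peptide], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def _looks_like_header(fields: Sequence[str]) -> bool:
    a = fields[0].strip().lower()
    b = fields[1].strip().lower()
    return a in {"id", "name", "identifier"} or b in {"sequence", "seq"}


def read_labeled_tsv(path, label: str) -> list:
    """Read a two-column (id, sequence) tab-separated file with one label.

    An optional header row (column names like ``id``/``sequence``) is
    detected and skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TSV file: {path}")
    peptides = []
    with open(path, newline="") as fh:
        for i, fields in enumerate(csv.reader(fh, delimiter="\t")):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue  # blank line
            if len(fields) != 2:
                raise PeptideValidationError(
                    f"{path}, line {i + 1}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if i == 0 and _looks_like_header(fields):
                continue
            peptides.append(Peptide(fields[0].strip(), fields[1].strip(), label))
    return peptides


def apply_length_filter(
    peptides: Sequence[Peptide], min_len: int, max_len: int
) -> list:
    """Keep peptides whose length is in [min_len, max_len], both inclusive."""
    if min_len < 1 or max_len < min_len:
        raise ValueError(f"invalid length bounds ({min_len}, {max_len})")
    return [p for p in peptides if min_len <= len(p) <= max_len]


def deduplicate(peptides: Sequence[Peptide], return_dropped: bool = False):
    """Drop later exact sequence duplicates, keeping first occurrences.

    Comparison is on the normalized (upper-cased) sequence string, so
    case-mixed duplicates collapse to one.
    """
    seen = set()
    kept = []
    dropped = 0
    for p in peptides:
        if p.sequence in seen:
            dropped += 1
            continue
        seen.add(p.sequence)
        kept.append(p)
    if return_dropped:
        return kept, dropped
    return kept


def build_dataset(
    positives: Sequence[Peptide],
    negatives: Sequence[Peptide],
    bounds: tuple = DEFAULT_LENGTH_BOUNDS,
    strict: bool = False,
) -> PeptideDataset:
    """Filter, deduplicate, and label a two-class dataset.

    Sequences present in both classes after filtering are kept in both with
    a warning; with ``strict=True`` the overlap is an error instead.
    """
    lo, hi = bounds
    pos = deduplicate(apply_length_filter(positives, lo, hi))
    neg = deduplicate(apply_length_filter(negatives, lo, hi))
    if not pos:
        raise DatasetError("positive class is empty after filtering")
    if not neg:
        raise DatasetError("negative class is empty after filtering")
    overlap = {p.sequence for p in pos} & {p.sequence for p in neg}
    if overlap:
        msg = (
            f"{len(overlap)} sequence(s) occur in both classes, e.g. "
            f"{sorted(overlap)[0]!r}"
        )
        if strict:
            raise DatasetError(msg)
        warnings.warn(msg, stacklevel=2)
    pos = [p.with_label(EPITOPE) for p in pos]
    neg = [p.with_label(NON_EPITOPE) for p in neg]
    return PeptideDataset(tuple(pos), tuple(neg), (lo, hi))
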