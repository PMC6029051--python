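"""Design utilities built on a trained model: virtual library screening,
single-residue analog generation, and protein window scanning for
immunomodulatory patches."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .motif_discovery import MotifMatch, motif_match
from .peptide_io import ALPHABET, EPITOPE, NON_EPITOPE, Peptide, UNLABELED
from .svm_model import FeaturizationFailure, ModelBundle, decision_scores


@dataclass(frozen=True)
class PredictionRecord:
    """One scored peptide: id, sequence, decision score, motif matches,
    and the label at the bundle threshold. Window-scan records also carry
    1-based inclusive (start, end) and 0-based half-open coordinates."""

    id: str
    sequence: str
    score: float
    label: str
    motif_matches: Tuple[MotifMatch, ...] = ()
    start: Optional[int] = None  # 1-based inclusive
    end: Optional[int] = None  # 1-based inclusive

    @property
    def span0(self) -> Optional[Tuple[int, int]]:
        """0-based half-open coordinates of a scan window."""
        if self.start is None:
            return None
        return (self.start - 1, self.end)


@dataclass(frozen=True)
class ScreenResult:
    """Library screening output: scored records (best first) plus any
    peptides that could not be featurized, reported rather than dropped."""

    records: Tuple[PredictionRecord, ...]
    failures: Tuple[Tuple[Peptide, str], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "id": r.id,
                    "sequence": r.sequence,
                    "start": r.start,
                    "end": r.end,
                    "score": r.score,
                    "motifs": ";".join(
                        m.motif.pattern for m in r.motif_matches
                    ),
                    "label": r.label,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["id", "sequence", "start", "end", "score", "motifs", "label"],
        )


def _record(bundle: ModelBundle, peptide: Peptide, score: float,
            start: Optional[int] = None, end: Optional[int] = None) -> PredictionRecord:
    matches: Tuple[MotifMatch, ...] = ()
    if bundle.motifs is not None:
        matches = tuple(motif_match(peptide.sequence, bundle.motifs.positive))
    label = EPITOPE if score >= bundle.threshold else NON_EPITOPE
    return PredictionRecord(
        peptide.id, peptide.sequence, float(score), label, matches, start, end
    )


def predict_library(bundle: ModelBundle, peptides: Sequence[Peptide]) -> ScreenResult:
    """Score a peptide library and rank it by decision score, descending.

    The sort is stable: ties keep input order. Peptides the bundle cannot
    featurize (e.g. shorter than a terminal window) are collected into
    ``failures`` with the reason, alongside — not instead of — the
    scored records.
    """
    scorable, failures = [], []
    for p in peptides:
        if len(p) >= bundle.feature_spec.min_peptide_length:
            scorable.append(p)
        else:
            failures.append(
                (p, f"length {len(p)} below the {bundle.feature_spec.name} "
                    f"minimum {bundle.feature_spec.min_peptide_length}")
            )
    scores = decision_scores(bundle, scorable)
    records = [_record(bundle, p, s) for p, s in zip(scorable, scores)]
    records.sort(key=lambda r: -r.score)  # stable: ties keep input order
    return ScreenResult(tuple(records), tuple(failures))


@dataclass(frozen=True)
class Analog:
    sequence: str
    position: int  # 1-based substituted position
    original: str
    replacement: str
    id: str


def generate_analogs(seq: str, seq_id: str = "query") -> List[Analog]:
    """All single-residue substitution analogs of a peptide.

    A length-L peptide yields exactly 19*L analogs, each at Hamming
    distance 1 from the input; the unmodified sequence is excluded.
    Order is deterministic: position-major, replacement residue in
    alphabet order. Analog ids encode the substitution, e.g.
    ``query_R3K`` for R at position 3 replaced by K.
    """
    bad = sorted(set(seq.upper()) - set(ALPHABET))
    if not seq or bad:
        raise ValueError(f"invalid residue(s) in query: {bad or 'empty sequence'}")
    seq = seq.upper()
    analogs = []
    for pos, original in enumerate(seq):
        for replacement in ALPHABET:
            if replacement == original:
                continue
            analogs.append(
                Analog(
                    seq[:pos] + replacement + seq[pos + 1 :],
                    pos + 1,
                    original,
                    replacement,
                    f"{seq_id}_{original}{pos + 1}{replacement}",
                )
            )
    return analogs


def predict_analogs(bundle: ModelBundle, seq: str, seq_id: str = "query") -> ScreenResult:
    """Generate all single-residue analogs and rank them by score."""
    analogs = generate_analogs(seq, seq_id)
    peptides = [Peptide(a.id, a.sequence, UNLABELED) for a in analogs]
    return predict_library(bundle, peptides)


def scan_protein(
    bundle: ModelBundle, protein: str, window: int, protein_id: str = "protein"
) -> List[PredictionRecord]:
    """Slide a window of fixed size along a protein and score each window.

    Produces L - window + 1 records at step 1, in sequence order, each
    with 1-based inclusive coordinates (0-based half-open available via
    ``PredictionRecord.span0``). The window must satisfy the bundle's
    length policy (>= the feature spec's minimum encodable length).
    """
    protein = protein.upper()
    bad = sorted(set(protein) - set(ALPHABET))
    if bad:
        raise ValueError(f"invalid residue(s) in protein: {bad}")
    if window < 3:
        raise ValueError("window must be >= 3")
    if window > len(protein):
        raise ValueError(
            f"window {window} longer than the protein ({len(protein)} residues)"
        )
    if window < bundle.feature_spec.min_peptide_length:
        raise ValueError(
            f"window {window} below the {bundle.feature_spec.name} minimum "
            f"length {bundle.feature_spec.min_peptide_length}"
        )
    peptides = [
        Peptide(f"{protein_id}_{i + 1}_{i + window}", protein[i : i + window])
        for i in range(len(protein) - window + 1)
    ]
    scores = decision_scores(bundle, peptides)
    return [
        _record(bundle, p, s, start=i + 1, end=i + window)
        for i, (p, s) in enumerate(zip(peptides, scores))
    ]
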