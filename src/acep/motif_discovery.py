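"""Class-exclusive ungapped motif discovery and rare n-mer analysis.

A motif here is a literal, contiguous residue string that occurs in at
least ``min_support`` sequences of one class and in *zero* sequences of
the contrast class. Exclusivity is the defining property: a single motif
hit is strong evidence for the class it is exclusive to. Matching is
plain substring containment; support counts sequences containing the
pattern at least once, not total occurrences.

The rare n-mer analysis asks whether a peptide set is built from n-mers
that are rare in a background proteome: background n-mers are ranked by
occurrence, split into near-equal rank bins (rarest first), and each
dataset's n-mer occurrence mass is apportioned across the bins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

POSITIVE_EXCLUSIVE = "positive_exclusive"
NEGATIVE_EXCLUSIVE = "negative_exclusive"


@dataclass(frozen=True)
class Motif:
    """An ungapped pattern with per-class containing-sequence counts."""

    pattern: str
    pos_count: int
    neg_count: int = 0


@dataclass(frozen=True)
class MotifSet:
    """Motifs exclusive to one class, sorted by support (descending)."""

    direction: str
    motifs: Tuple[Motif, ...]
    min_support: int
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if self.direction not in (POSITIVE_EXCLUSIVE, NEGATIVE_EXCLUSIVE):
            raise ValueError(f"unknown direction {self.direction!r}")
        object.__setattr__(self, "motifs", tuple(self.motifs))
        patterns = [m.pattern for m in self.motifs]
        if len(set(patterns)) != len(patterns):
            raise ValueError("duplicate motif patterns")

    def __len__(self) -> int:
        return len(self.motifs)

    def patterns(self) -> List[str]:
        return [m.pattern for m in self.motifs]

    def top(self, n: int) -> "MotifSet":
        return MotifSet(
            self.direction, self.motifs[:n], self.min_support, self.min_len, self.max_len
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.pattern, m.pos_count, m.neg_count) for m in self.motifs],
            columns=["pattern", "pos_count", "neg_count"],
        )


def _substrings(seq: str, min_len: int, max_len: int) -> set:
    out = set()
    L = len(seq)
    for n in range(min_len, min(max_len, L) + 1):
        for i in range(L - n + 1):
            out.add(seq[i : i + n])
    return out


def _support_counts(seqs: Sequence[str], min_len: int, max_len: int) -> Counter:
    """Number of sequences containing each substring (set semantics)."""
    support: Counter = Counter()
    for s in seqs:
        support.update(_substrings(s, min_len, max_len))
    return support


def find_exclusive_motifs(
    positives: Sequence[str],
    negatives: Sequence[str],
    min_support: Optional[int] = None,
    min_len: int = 3,
    max_len: int = 8,
    prune: bool = True,
) -> MotifSet:
    """Enumerate ungapped motifs exclusive to the positive class.

    Every reported pattern is contained in >= ``min_support`` positive
    sequences and in zero negative sequences. ``min_support`` defaults to
    max(3, 1% of the positive set). With ``prune=True`` a pattern is
    dropped when one of its own proper substrings is also exclusive with
    the same support (the longer pattern adds no discrimination); the
    shortest informative form is kept. Output is sorted by support
    descending, then lexicographically.

    Motifs exclusive to the *negative* class are found by swapping the
    argument order (the returned counts then refer to the negative class).
    """
    positives = [str(s) for s in positives]
    negatives = [str(s) for s in negatives]
    if not positives:
        raise ValueError("positive set is empty")
    if min_len < 2 or max_len < min_len:
        raise ValueError(f"invalid motif length range ({min_len}, {max_len})")
    if min_support is None:
        min_support = max(3, int(round(0.01 * len(positives))))
    if min_support < 1:
        raise ValueError("min_support must be >= 1")

    support = _support_counts(positives, min_len, max_len)
    neg_substrings = set()
    for s in negatives:
        neg_substrings |= _substrings(s, min_len, max_len)

    exclusive = {
        pat: cnt
        for pat, cnt in support.items()
        if cnt >= min_support and pat not in neg_substrings
    }

    if prune:
        kept = {}
        for pat, cnt in exclusive.items():
            redundant = False
            for n in range(min_len, len(pat)):
                for i in range(len(pat) - n + 1):
                    sub = pat[i : i + n]
                    if exclusive.get(sub) == cnt:
                        redundant = True
                        break
                if redundant:
                    break
            if not redundant:
                kept[pat] = cnt
        exclusive = kept

    motifs = tuple(
        Motif(pat, cnt, 0)
        for pat, cnt in sorted(exclusive.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return MotifSet(POSITIVE_EXCLUSIVE, motifs, min_support, min_len, max_len)


@dataclass(frozen=True)
class MotifMatch:
    motif: Motif
    positions: Tuple[int, ...]  # 1-based start positions


def motif_match(seq: str, motif_set: MotifSet) -> List[MotifMatch]:
    """All motifs of the set occurring in ``seq``, with 1-based positions.

    A motif occurring several times is reported once, carrying every
    start position.
    """
    hits = []
    for m in motif_set.motifs:
        positions = []
        start = seq.find(m.pattern)
        while start != -1:
            positions.append(start + 1)
            start = seq.find(m.pattern, start + 1)
        if positions:
            hits.append(MotifMatch(m, tuple(positions)))
    return hits


def motif_score(
    seq: str,
    pos_motifs: Optional[MotifSet],
    neg_motifs: Optional[MotifSet] = None,
    weight: float = 0.5,
) -> float:
    """Additive motif evidence for one sequence.

    +``weight`` if the sequence contains any positive-exclusive motif,
    -``weight`` if it contains any negative-exclusive motif; matching
    both cancels to zero. The contribution is per motif *set*, not per
    motif, so a sequence riddled with positive motifs scores the same as
    one with a single hit.
    """
    if weight <= 0:
        raise ValueError("weight must be > 0")
    score = 0.0
    if pos_motifs is not None and any(m.pattern in seq for m in pos_motifs.motifs):
        score += weight
    if neg_motifs is not None and any(m.pattern in seq for m in neg_motifs.motifs):
        score -= weight
    return score


def count_nmers(sequences: Iterable[str], n: int) -> Counter:
    """Overlapping n-mer occurrence counts across a set of sequences."""
    if n < 1:
        raise ValueError("n must be >= 1")
    counts: Counter = Counter()
    for seq in sequences:
        for i in range(len(seq) - n + 1):
            counts[seq[i : i + n]] += 1
    return counts


@dataclass(frozen=True)
class NmerBinTable:
    """Occurrence-rarity bin table for an n-mer family.

    Distinct background n-mers are sorted by ascending background count
    (ties broken lexicographically) and split into ``n_bins`` near-equal
    rank bins; bin 1 holds the rarest n-mers. ``percentages[d][b]`` is the
    share (percent) of dataset *d*'s total n-mer occurrences carried by
    n-mers of bin *b*; the ``unseen`` entry collects dataset n-mers absent
    from the background. Each dataset's bins + unseen sum to 100.
    """

    n: int
    n_bins: int
    bin_ranges: Tuple[Tuple[int, int], ...]  # 1-based rank ranges
    percentages: dict  # dataset name -> list of per-bin percentages
    unseen: dict  # dataset name -> percentage

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, (lo, hi) in enumerate(self.bin_ranges):
            rows.append(
                {
                    "bin": b + 1,
                    "rank_lo": lo,
                    "rank_hi": hi,
                    **{d: self.percentages[d][b] for d in self.percentages},
                }
            )
        rows.append(
            {"bin": "unseen", "rank_lo": None, "rank_hi": None, **self.unseen}
        )
        return pd.DataFrame(rows)


def rare_nmer_bins(
    background: Counter,
    positives: Sequence[str],
    negatives: Sequence[str],
    n: int,
    n_bins: int = 8,
) -> NmerBinTable:
    """Apportion each dataset's n-mer occurrences across background-rarity bins."""
    if not background:
        raise ValueError("background n-mer counts are empty")
    distinct = sorted(background, key=lambda k: (background[k], k))
    if n_bins < 2 or n_bins > len(distinct):
        raise ValueError(
            f"n_bins={n_bins} invalid for {len(distinct)} distinct background n-mers"
        )
    bin_of: Dict[str, int] = {}
    ranges = []
    rank = 0
    for b, chunk in enumerate(np.array_split(np.asarray(distinct, dtype=object), n_bins)):
        ranges.append((rank + 1, rank + len(chunk)))
        for nm in chunk:
            bin_of[nm] = b
        rank += len(chunk)

    datasets = {
        "background": background,
        "positives": count_nmers(positives, n),
        "negatives": count_nmers(negatives, n),
    }
    percentages, unseen = {}, {}
    for name, counts in datasets.items():
        total = sum(counts.values())
        per_bin = [0.0] * n_bins
        missing = 0.0
        for nm, c in counts.items():
            if nm in bin_of:
                per_bin[bin_of[nm]] += c
            else:
                missing += c
        if total > 0:
            per_bin = [100.0 * v / total for v in per_bin]
            missing = 100.0 * missing / total
        percentages[name] = per_bin
        unseen[name] = missing
    return NmerBinTable(n, n_bins, tuple(ranges), percentages, unseen)
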