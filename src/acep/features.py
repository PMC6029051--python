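"""Fixed-length numeric encodings of variable-length peptides.

Machine-learning models need a fixed-length vector per peptide, while
peptide lengths vary (3-30 residues here). Three encoder families bridge
the gap:

* **Composition** (``AAC``/``DPC``/``TPC``): percentages of single
  residues, overlapping dipeptides, or overlapping tripeptides over the
  whole sequence or a terminal window. Vector lengths 20 / 400 / 8000;
  entries are non-negative and sum to 100. Denominators are the number of
  overlapping windows (L, L-1, L-2).
* **Binary profile** (``BIN``): positional one-hot encoding of a terminal
  window, 20 slots per position in canonical alphabet order, N-terminal
  block first. A window of k residues yields 20*k values (40*k when both
  termini are used).

Terminal regions are named after the field convention: ``N_5`` is the
first five residues, ``C_5`` the last five, ``N5C5`` (region ``NC``,
k=5) both. When k <= L < 2k the two windows of an ``NC`` region overlap
in the middle of the peptide; both windows are still valid individually,
so the peptide is encodable. Peptides shorter than k cannot be encoded
and are either dropped with a warning (training) or rejected with an
error (prediction) — see :func:`featurize_peptides`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .peptide_io import AA_INDEX, ALPHABET, Peptide

KINDS = ("AAC", "DPC", "TPC", "BIN")
REGIONS = ("full", "N", "C", "NC")

#: Ordered dipeptide and tripeptide labels (AA, AC, ..., YY / AAA ... YYY).
DIPEPTIDES = tuple(a + b for a in ALPHABET for b in ALPHABET)
TRIPEPTIDES = tuple(a + b + c for a in ALPHABET for b in ALPHABET for c in ALPHABET)
_DP_INDEX = {dp: i for i, dp in enumerate(DIPEPTIDES)}
_TP_INDEX = {tp: i for i, tp in enumerate(TRIPEPTIDES)}


class FeatureError(ValueError):
    """A peptide cannot be encoded under the requested feature spec."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declarative description of an encoder.

    Parameters
    ----------
    kind:
        "AAC", "DPC", "TPC" (composition) or "BIN" (binary profile).
    region:
        "full" for the whole sequence, or "N"/"C"/"NC" for terminal
        windows of size ``k``.
    k:
        Terminal window size; ignored for region "full".
    nc_dpc:
        How to combine the two segments of an NC-region DPC: "average"
        encodes each segment separately and averages the two 400-vectors
        (no fictitious N-to-C junction dipeptide); "concat" encodes the
        concatenated 2k-mer, junction included.
    """

    kind: str
    region: str = "full"
    k: int = 0
    nc_dpc: str = "average"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.kind == "TPC" and self.region != "full":
            raise ValueError("TPC is an analysis feature: region must be 'full'")
        if self.kind == "BIN" and self.region == "full":
            raise ValueError("BIN requires a fixed terminal window (N/C/NC)")
        if self.region != "full" and self.k < 1:
            raise ValueError("terminal regions require k >= 1")
        if self.nc_dpc not in ("average", "concat"):
            raise ValueError(f"unknown nc_dpc policy {self.nc_dpc!r}")

    @property
    def vector_length(self) -> int:
        if self.kind == "AAC":
            return 20
        if self.kind == "DPC":
            return 400
        if self.kind == "TPC":
            return 8000
        # BIN
        return 40 * self.k if self.region == "NC" else 20 * self.k

    @property
    def min_peptide_length(self) -> int:
        """Shortest peptide this spec can encode."""
        if self.region != "full":
            return self.k
        return {"AAC": 1, "DPC": 2, "TPC": 3}[self.kind]

    @property
    def name(self) -> str:
        if self.region == "full":
            return self.kind
        if self.region == "NC":
            return f"N{self.k}C{self.k} {self.kind}"
        return f"{self.region}{self.k} {self.kind}"

    def feature_names(self) -> List[str]:
        if self.kind == "AAC":
            base = [f"AAC_{a}" for a in ALPHABET]
        elif self.kind == "DPC":
            base = [f"DPC_{d}" for d in DIPEPTIDES]
        elif self.kind == "TPC":
            base = [f"TPC_{t}" for t in TRIPEPTIDES]
        else:
            positions = []
            if self.region in ("N", "NC"):
                positions += [f"N{i + 1}" for i in range(self.k)]
            if self.region in ("C", "NC"):
                positions += [f"C{i + 1}" for i in range(self.k)]
            tag = f"BIN_{self.region}{self.k}"
            return [f"{tag}_{p}_{a}" for p in positions for a in ALPHABET]
        if self.region == "full":
            return base
        prefix = f"N{self.k}C{self.k}" if self.region == "NC" else f"{self.region}{self.k}"
        return [f"{prefix}_{b}" for b in base]


def amino_acid_composition(seq: str) -> np.ndarray:
    """Percent single-residue composition, length 20."""
    if not seq:
        raise FeatureError("cannot compute AAC of an empty sequence")
    v = np.zeros(20)
    for aa in seq:
        v[AA_INDEX[aa]] += 1.0
    return v * (100.0 / len(seq))


def dipeptide_composition(seq: str) -> np.ndarray:
    """Percent overlapping-dipeptide composition, length 400."""
    if len(seq) < 2:
        raise FeatureError(f"sequence {seq!r} too short for DPC (need >= 2)")
    v = np.zeros(400)
    for i in range(len(seq) - 1):
        v[_DP_INDEX[seq[i : i + 2]]] += 1.0
    return v * (100.0 / (len(seq) - 1))


def tripeptide_composition(seq: str) -> np.ndarray:
    """Percent overlapping-tripeptide composition, length 8000."""
    if len(seq) < 3:
        raise FeatureError(f"sequence {seq!r} too short for TPC (need >= 3)")
    v = np.zeros(8000)
    for i in range(len(seq) - 2):
        v[_TP_INDEX[seq[i : i + 3]]] += 1.0
    return v * (100.0 / (len(seq) - 2))


def terminal_segments(seq: str, region: str, k: int) -> List[str]:
    """Extract the terminal window(s) of a peptide.

    ``N`` -> [first k residues]; ``C`` -> [last k]; ``NC`` -> [first k,
    last k] (the two may overlap when k <= len < 2k). A peptide shorter
    than k raises :class:`FeatureError`.
    """
    if region == "full":
        return [seq]
    if len(seq) < k:
        raise FeatureError(
            f"sequence {seq!r} (length {len(seq)}) is shorter than the "
            f"terminal window k={k}"
        )
    if region == "N":
        return [seq[:k]]
    if region == "C":
        return [seq[-k:]]
    return [seq[:k], seq[-k:]]


def terminal_subsequence(seq: str, region: str, k: int) -> str:
    """Concatenated terminal window(s) (N first for NC regions)."""
    return "".join(terminal_segments(seq, region, k))


def binary_profile(seq: str, region: str, k: int) -> np.ndarray:
    """Positional one-hot encoding of the terminal window(s).

    Each encoded position contributes a 20-slot block in canonical
    alphabet order; blocks are concatenated N-terminal first.
    """
    residues = terminal_subsequence(seq, region, k)
    v = np.zeros(20 * len(residues))
    for pos, aa in enumerate(residues):
        v[20 * pos + AA_INDEX[aa]] = 1.0
    return v


def encode(seq: str, spec: FeatureSpec) -> np.ndarray:
    """Encode one sequence under a feature spec."""
    if spec.kind == "BIN":
        return binary_profile(seq, spec.region, spec.k)
    if spec.kind == "TPC":
        return tripeptide_composition(seq)
    if spec.region == "full":
        return amino_acid_composition(seq) if spec.kind == "AAC" else dipeptide_composition(seq)
    segments = terminal_segments(seq, spec.region, spec.k)
    if spec.kind == "AAC":
        # pooled residues: AAC of the concatenated window(s)
        return amino_acid_composition("".join(segments))
    # DPC on terminal windows
    if spec.region != "NC" or spec.nc_dpc == "concat":
        return dipeptide_composition("".join(segments))
    return (dipeptide_composition(segments[0]) + dipeptide_composition(segments[1])) / 2.0


def featurize_peptides(
    peptides: Sequence[Peptide],
    spec: FeatureSpec,
    on_short: str = "error",
) -> Tuple[np.ndarray, List[Peptide], List[Peptide]]:
    """Encode a batch of peptides into a (n, d) matrix.

    Peptides shorter than the spec's minimum length are handled per
    ``on_short``: "error" raises naming the offenders, "drop" excludes
    them with a warning. Returns (matrix, encoded peptides, excluded
    peptides).
    """
    if on_short not in ("error", "drop"):
        raise ValueError(f"unknown on_short policy {on_short!r}")
    ok, short = [], []
    for p in peptides:
        (ok if len(p) >= spec.min_peptide_length else short).append(p)
    if short:
        ids = ", ".join(p.id for p in short[:5])
        more = "" if len(short) <= 5 else f" (+{len(short) - 5} more)"
        msg = (
            f"{len(short)} peptide(s) shorter than the {spec.name} minimum "
            f"length {spec.min_peptide_length}: {ids}{more}"
        )
        if on_short == "error":
            raise FeatureError(msg)
        warnings.warn(msg, stacklevel=2)
    if not ok:
        return np.empty((0, spec.vector_length)), [], short
    X = np.vstack([encode(p.sequence, spec) for p in ok])
    return X, ok, short


def feature_table(peptides: Sequence[Peptide], spec: FeatureSpec):
    """Feature matrix as a pandas DataFrame indexed by peptide id."""
    import pandas as pd

    X, ok, _ = featurize_peptides(peptides, spec, on_short="error")
    return pd.DataFrame(X, index=[p.id for p in ok], columns=spec.feature_names())
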