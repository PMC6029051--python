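"""Dataset characterization: composition contrasts and terminal residue
preferences between epitopes and non-epitopes.

Composition comparison follows the per-peptide-first convention: the
percent composition is computed for every peptide and then averaged
within each class, so short and long peptides contribute equally. Class
differences are tested per feature with Welch's (unequal-variance)
two-sample t-test and corrected for multiplicity across the feature
family (20 residues, 400 dipeptides, or 8000 tripeptides).

Terminal preference mirrors the two-sample-logo statistic family: per
terminal position and residue, the class frequency difference with a
two-proportion z-test. Positive differences mean the residue is enriched
in epitopes at that position; the table (not a logo graphic) is the
product.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .features import (
    amino_acid_composition,
    dipeptide_composition,
    tripeptide_composition,
    FeatureSpec,
)
from .peptide_io import AA_INDEX, ALPHABET

_ENCODERS = {
    "AAC": amino_acid_composition,
    "DPC": dipeptide_composition,
    "TPC": tripeptide_composition,
}


def _class_matrix(sequences: Sequence[str], kind: str) -> np.ndarray:
    enc = _ENCODERS[kind]
    return np.vstack([enc(s) for s in sequences])


def composition_comparison(
    positives: Sequence[str],
    negatives: Sequence[str],
    background: Optional[Sequence[str]] = None,
    kind: str = "AAC",
    adjust: str = "bh",
) -> pd.DataFrame:
    """Per-feature class means, differences, and (adjusted) p-values.

    Returns one row per feature of the chosen composition kind with
    columns: feature, mean_pos, mean_neg, mean_background (NaN when no
    background is given), difference (pos - neg), p_value,
    adjusted_p_value. Features with zero variance in both classes get
    p = 1. ``adjust`` is "bh" (Benjamini-Hochberg, default) or
    "bonferroni".
    """
    if kind not in _ENCODERS:
        raise ValueError(f"unknown composition kind {kind!r}")
    if not positives or not negatives:
        raise ValueError("both classes must be non-empty")
    if adjust not in ("bh", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")

    pos = _class_matrix(positives, kind)
    neg = _class_matrix(negatives, kind)
    names = FeatureSpec(kind).feature_names()

    mean_pos = pos.mean(axis=0)
    mean_neg = neg.mean(axis=0)
    if background is not None:
        mean_bg = _class_matrix(background, kind).mean(axis=0)
    else:
        mean_bg = np.full(len(names), np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(pos, neg, axis=0, equal_var=False)
    # zero variance in both classes -> test undefined -> report p = 1
    degenerate = (pos.var(axis=0) == 0) & (neg.var(axis=0) == 0)
    pvals = np.where(degenerate | ~np.isfinite(pvals), 1.0, pvals)

    method = "fdr_bh" if adjust == "bh" else "bonferroni"
    _, adjusted, _, _ = multipletests(pvals, method=method)

    return pd.DataFrame(
        {
            "feature": names,
            "mean_pos": mean_pos,
            "mean_neg": mean_neg,
            "mean_background": mean_bg,
            "difference": mean_pos - mean_neg,
            "p_value": pvals,
            "adjusted_p_value": adjusted,
        }
    )


def terminal_preference(
    positives: Sequence[str],
    negatives: Sequence[str],
    k: int = 3,
    terminus: str = "N",
) -> pd.DataFrame:
    """Positional residue frequencies at a terminus, with class contrasts.

    For each position 1..k (counted inward from the chosen terminus) and
    each residue: the frequency in each class, the difference
    (pos - neg), and a two-proportion z-test p-value. All sequences must
    be at least k residues long.
    """
    if terminus not in ("N", "C"):
        raise ValueError(f"terminus must be 'N' or 'C', got {terminus!r}")
    if not positives or not negatives:
        raise ValueError("both classes must be non-empty")
    for group_name, group in (("positive", positives), ("negative", negatives)):
        short = [s for s in group if len(s) < k]
        if short:
            raise ValueError(
                f"{len(short)} {group_name} sequence(s) shorter than k={k}, "
                f"e.g. {short[0]!r}"
            )

    def window(s: str) -> str:
        return s[:k] if terminus == "N" else s[-k:]

    n_pos, n_neg = len(positives), len(negatives)
    rows = []
    for p in range(k):
        pos_counts = np.zeros(20, dtype=int)
        neg_counts = np.zeros(20, dtype=int)
        for s in positives:
            pos_counts[AA_INDEX[window(s)[p]]] += 1
        for s in negatives:
            neg_counts[AA_INDEX[window(s)[p]]] += 1
        for a, aa in enumerate(ALPHABET):
            cp, cn = int(pos_counts[a]), int(neg_counts[a])
            if cp + cn == 0 or (cp == n_pos and cn == n_neg):
                pval = 1.0  # identical degenerate proportions
            else:
                _, pval = proportions_ztest([cp, cn], [n_pos, n_neg])
                if not np.isfinite(pval):
                    pval = 1.0
            rows.append(
                {
                    "terminus": terminus,
                    "position": p + 1,
                    "residue": aa,
                    "freq_pos": cp / n_pos,
                    "freq_neg": cn / n_neg,
                    "difference": cp / n_pos - cn / n_neg,
                    "p_value": float(pval),
                }
            )
    return pd.DataFrame(rows)
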