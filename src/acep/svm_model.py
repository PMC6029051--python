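"""RBF-kernel SVM classification of peptides with threshold-on-score
decisions, fivefold cross-validation, and the repeated-split (bagging)
evaluation protocol.

The classifier is a support vector machine with a radial basis function
kernel, parameterized the way the SVM-light lineage of epitope predictors
names its knobs:

* ``g`` — RBF kernel width (gamma),
* ``c`` — error/margin trade-off,
* ``j`` — cost factor by which training errors on positive examples
  outweigh errors on negative examples (realized as a positive-class
  error weight),
* ``threshold`` — decision-score cutoff; a peptide is called an epitope
  iff its score is >= threshold (ties go to the positive class).

Hybrid models add a motif evidence term to the raw SVM decision score:
+w for containing a positive-exclusive motif, -w for a negative-exclusive
one (see :func:`acep.motif_discovery.motif_score`).

Evaluation follows the internal/external protocol: the dataset is split
~80/20 per class; the internal part is scored by stratified fivefold
cross-validation with all held-out scores pooled before computing
metrics (each sequence is tested exactly once); the external part is
scored by a model trained on the whole internal part. Repeating the
split 10 times with fresh randomness and reporting mean +/- SD of every
metric is the bagging protocol.

Features enter the SVM on their natural percent (or 0/1) scale without
standardization; the gamma grid is tuned to that scale.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import __version__
from .features import FeatureSpec, featurize_peptides
from .motif_discovery import (
    MotifSet,
    find_exclusive_motifs,
    motif_score,
)
from .peptide_io import EPITOPE, NON_EPITOPE, Peptide, PeptideDataset

BUNDLE_FORMAT_VERSION = 1

#: Default threshold grid: -1.5 to +1.5 in steps of 0.1.
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(-1.5, 1.5 + 1e-9, 0.1), 10))

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "mcc", "auroc")


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters plus the decision threshold."""

    g: float
    c: float = 1.0
    j: float = 1.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.g <= 0 or self.c <= 0 or self.j <= 0:
            raise ValueError("g, c and j must all be > 0")


@dataclass(frozen=True)
class MotifConfig:
    """How to discover class-exclusive motifs on a training set."""

    min_support: Optional[int] = None  # None -> max(3, 1% of positives)
    min_len: int = 3
    max_len: int = 8
    weight: float = 0.5


@dataclass(frozen=True)
class MotifAugment:
    """Discovered motif sets plus the score weight, attached to a model."""

    positive: MotifSet
    negative: Optional[MotifSet]
    weight: float = 0.5

    def score(self, seq: str) -> float:
        return motif_score(seq, self.positive, self.negative, self.weight)


def discover_motif_augment(
    internal: PeptideDataset, config: MotifConfig
) -> MotifAugment:
    """Find positive- and negative-exclusive motifs on a training set."""
    pos_seqs = [p.sequence for p in internal.positives]
    neg_seqs = [p.sequence for p in internal.negatives]
    pos_set = find_exclusive_motifs(
        pos_seqs, neg_seqs, config.min_support, config.min_len, config.max_len
    )
    neg_set = find_exclusive_motifs(
        neg_seqs, pos_seqs, config.min_support, config.min_len, config.max_len
    )
    return MotifAugment(pos_set, neg_set, config.weight)


@dataclass
class ModelBundle:
    """A trained, self-describing predictor: feature spec + optional motif
    sets + SVM parameters + fitted state + provenance."""

    feature_spec: FeatureSpec
    svm_config: SVMConfig
    estimator: SVC
    motifs: Optional[MotifAugment] = None
    provenance: Dict = field(default_factory=dict)

    @property
    def threshold(self) -> float:
        return self.svm_config.threshold

    def with_threshold(self, threshold: float) -> "ModelBundle":
        return replace(self, svm_config=replace(self.svm_config, threshold=threshold))


class FeaturizationFailure(ValueError):
    """Prediction-time featurization failed for one or more peptides."""


def _labels_to_y(peptides: Sequence[Peptide]) -> np.ndarray:
    y = np.empty(len(peptides), dtype=int)
    for i, p in enumerate(peptides):
        if p.label == EPITOPE:
            y[i] = 1
        elif p.label == NON_EPITOPE:
            y[i] = 0
        else:
            raise ValueError(f"peptide {p.id!r} is unlabeled")
    return y


def _dataset_digest(peptides: Sequence[Peptide]) -> str:
    h = hashlib.sha256()
    for p in sorted(peptides, key=lambda q: (q.sequence, q.label)):
        h.update(f"{p.sequence}\t{p.label}\n".encode())
    return h.hexdigest()[:16]


def _make_estimator(config: SVMConfig) -> SVC:
    # j-fold up-weighting of positive-class training errors (SVM-light's
    # cost-factor semantics).
    return SVC(
        kernel="rbf",
        gamma=config.g,
        C=config.c,
        class_weight={0: 1.0, 1: config.j},
    )


def split_dataset(
    dataset: PeptideDataset, train_fraction: float = 0.8, seed: int = 0
) -> Tuple[PeptideDataset, PeptideDataset]:
    """Stratified random split into internal (train) and external (held-out)
    parts.

    The external class size is round((1 - f) * n_class), half-up, sampled
    uniformly without replacement; a 304/385 dataset at f=0.8 therefore
    splits into internal 243/308 and external 61/77.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    parts = {"internal": [], "external": []}
    for group in (dataset.positives, dataset.negatives):
        n = len(group)
        n_ext = int(np.floor((1 - train_fraction) * n + 0.5))
        if n_ext == 0 or n_ext == n:
            raise ValueError(
                f"split would empty a class (n={n}, train_fraction={train_fraction})"
            )
        ext_idx = set(rng.choice(n, size=n_ext, replace=False).tolist())
        parts["internal"].append([p for i, p in enumerate(group) if i not in ext_idx])
        parts["external"].append([p for i, p in enumerate(group) if i in ext_idx])
    internal = PeptideDataset(
        tuple(parts["internal"][0]), tuple(parts["internal"][1]), dataset.length_bounds
    )
    external = PeptideDataset(
        tuple(parts["external"][0]), tuple(parts["external"][1]), dataset.length_bounds
    )
    return internal, external


def train(
    internal: PeptideDataset,
    spec: FeatureSpec,
    config: SVMConfig,
    motifs: Optional[MotifAugment] = None,
    seed: Optional[int] = None,
) -> ModelBundle:
    """Fit an RBF-SVM on the internal dataset under a feature spec.

    Peptides shorter than the spec's terminal window are excluded from
    training with a warning (they cannot be encoded); the exclusion is
    recorded in the bundle's provenance.
    """
    peptides = internal.all_peptides()
    X, ok, short = featurize_peptides(peptides, spec, on_short="drop")
    y = _labels_to_y(ok)
    if y.min() == y.max():
        raise ValueError("training set must contain both classes after featurization")
    est = _make_estimator(config)
    est.fit(X, y)
    provenance = {
        "software_version": __version__,
        "seed": seed,
        "training_digest": _dataset_digest(ok),
        "n_train_pos": int(y.sum()),
        "n_train_neg": int(len(y) - y.sum()),
        "n_excluded_short": len(short),
    }
    return ModelBundle(spec, config, est, motifs, provenance)


def decision_scores(bundle: ModelBundle, peptides: Sequence[Peptide]) -> np.ndarray:
    """Signed decision score per peptide (positive side = epitope).

    Hybrid bundles add the motif evidence term to the raw SVM score.
    Peptides that cannot be featurized raise a
    :class:`FeaturizationFailure` naming them — they are never silently
    skipped.
    """
    if not peptides:
        return np.empty(0)
    try:
        X, ok, _ = featurize_peptides(peptides, bundle.feature_spec, on_short="error")
    except Exception as exc:
        raise FeaturizationFailure(str(exc)) from exc
    scores = bundle.estimator.decision_function(X)
    if bundle.motifs is not None:
        scores = scores + np.array([bundle.motifs.score(p.sequence) for p in ok])
    return scores


def classify(bundle: ModelBundle, peptides: Sequence[Peptide]) -> List[str]:
    """Label each peptide epitope/non_epitope at the bundle's threshold."""
    scores = decision_scores(bundle, peptides)
    return [EPITOPE if s >= bundle.threshold else NON_EPITOPE for s in scores]


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion-derived metrics for one evaluation.

    Sensitivity/specificity/accuracy are percentages; MCC is in [-1, 1]
    with the zero-marginal convention (MCC = 0 when any row or column of
    the confusion matrix is empty); AUROC is the rank (Mann-Whitney)
    statistic with ties counted half.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auroc: float

    def as_dict(self) -> Dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def _mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    denom_sq = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom_sq)


def compute_metrics(
    y_true: Sequence[int], scores: Sequence[float], threshold: float
) -> EvalMetrics:
    """Threshold the scores and derive the full confusion-based metric set.

    ``y_true`` uses 1 for epitopes and 0 for non-epitopes. AUROC needs
    both classes present.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} labels, {s.shape[0]} scores")
    if y.min() == y.max():
        raise ValueError("AUROC undefined: only one class present")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / len(y)
    return EvalMetrics(
        tp, fp, tn, fn, sens, spec, acc,
        _mcc_from_counts(tp, fp, tn, fn),
        float(roc_auc_score(y, s)),
    )


def select_threshold(
    y_true: Sequence[int],
    scores: Sequence[float],
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> float:
    """Pick the grid threshold maximizing MCC; ties prefer the smallest
    sensitivity-specificity gap, then the smallest threshold."""
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    best = None
    for t in sorted(grid):
        m = compute_metrics(y_true, scores, t)
        key = (-round(m.mcc, 12), round(abs(m.sensitivity - m.specificity), 12), t)
        if best is None or key < best[0]:
            best = (key, t)
    return best[1]


def _fold_motif_augment(
    peptides: Sequence[Peptide], config: MotifConfig
) -> MotifAugment:
    pos = [p.sequence for p in peptides if p.label == EPITOPE]
    neg = [p.sequence for p in peptides if p.label == NON_EPITOPE]
    pos_set = find_exclusive_motifs(
        pos, neg, config.min_support, config.min_len, config.max_len
    )
    neg_set = find_exclusive_motifs(
        neg, pos, config.min_support, config.min_len, config.max_len
    )
    return MotifAugment(pos_set, neg_set, config.weight)


def _cv_scores(
    internal: PeptideDataset,
    spec: FeatureSpec,
    config: SVMConfig,
    seed: int,
    motifs: Optional[MotifAugment] = None,
    motif_config: Optional[MotifConfig] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Pooled held-out decision scores from stratified fivefold CV."""
    if motifs is not None and motif_config is not None:
        raise ValueError("pass fixed motif sets or a motif config, not both")
    peptides = internal.all_peptides()
    X, ok, _ = featurize_peptides(peptides, spec, on_short="drop")
    y = _labels_to_y(ok)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 5:
        raise ValueError(
            f"need >= 5 peptides per class for fivefold CV, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    pooled = np.empty(len(y))
    for train_idx, test_idx in skf.split(X, y):
        est = _make_estimator(config)
        est.fit(X[train_idx], y[train_idx])
        fold_scores = est.decision_function(X[test_idx])
        if motif_config is not None:
            # leakage-free variant: motifs mined on the training folds only
            aug = _fold_motif_augment([ok[i] for i in train_idx], motif_config)
            fold_scores = fold_scores + np.array(
                [aug.score(ok[i].sequence) for i in test_idx]
            )
        pooled[test_idx] = fold_scores
    if motifs is not None:
        pooled = pooled + np.array([motifs.score(p.sequence) for p in ok])
    return y, pooled


def fivefold_cv(
    internal: PeptideDataset,
    spec: FeatureSpec,
    config: SVMConfig,
    seed: int = 0,
    motifs: Optional[MotifAugment] = None,
    motif_config: Optional[MotifConfig] = None,
) -> EvalMetrics:
    """Stratified fivefold cross-validation on the internal dataset.

    Each sequence is held out exactly once; all held-out scores are pooled
    and the metrics computed once at the configured threshold (pooling
    keeps sensitivity/specificity well defined with small classes).

    Hybrid models come in two flavours: ``motifs`` adds a *fixed*,
    externally mined motif score to every held-out prediction (the classic
    protocol, in which exclusive motifs are catalogued once on the whole
    dataset — optimistic because held-out sequences contributed to the
    catalogue); ``motif_config`` re-mines motifs on the four training
    folds of each split instead, keeping the held-out fold unseen.
    """
    y, scores = _cv_scores(internal, spec, config, seed, motifs, motif_config)
    return compute_metrics(y, scores, config.threshold)


@dataclass(frozen=True)
class BaggingRound:
    index: int
    seed: int
    internal: EvalMetrics
    external: EvalMetrics


@dataclass(frozen=True)
class BaggingReport:
    """Per-round internal/external metrics plus mean +/- SD summaries."""

    rounds: Tuple[BaggingRound, ...]

    def summary(self) -> pd.DataFrame:
        """Mean and sample SD (ddof=1) of each metric over rounds."""
        rows = []
        for split in ("internal", "external"):
            for metric in METRIC_NAMES:
                vals = np.array(
                    [getattr(getattr(r, split), metric) for r in self.rounds]
                )
                rows.append(
                    {
                        "split": split,
                        "metric": metric,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def mean(self, split: str, metric: str) -> float:
        df = self.summary()
        row = df[(df["split"] == split) & (df["metric"] == metric)]
        return float(row["mean"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rounds:
            for split in ("internal", "external"):
                rows.append(
                    {"round": r.index, "seed": r.seed, "split": split,
                     **getattr(r, split).as_dict()}
                )
        return pd.DataFrame(rows)


def derive_seed(master_seed: int, *keys: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and keys."""
    state = np.random.SeedSequence([int(master_seed), *map(int, keys)])
    return int(state.generate_state(1)[0] % (2**31))


def bagging_evaluate(
    main: PeptideDataset,
    spec: FeatureSpec,
    config: SVMConfig,
    n_rounds: int = 10,
    train_fraction: float = 0.8,
    master_seed: int = 0,
    motifs: Optional[MotifAugment] = None,
    motif_config: Optional[MotifConfig] = None,
) -> BaggingReport:
    """Repeat the 80/20 internal/external protocol ``n_rounds`` times.

    Per round: split with a seed derived from (master_seed, round);
    internal metrics come from pooled fivefold CV; external metrics from a
    model trained on the whole internal part. The report is bitwise
    reproducible from the master seed.

    Hybrid models: pass ``motifs`` for the classic protocol (one fixed
    motif catalogue, typically mined once on the main dataset and shared
    by every round and both splits — optimistic, since evaluated
    sequences contributed to the catalogue) or ``motif_config`` for the
    leakage-free variant (motifs re-mined per round on the internal
    split only, and per training fold inside the internal CV).
    """
    if n_rounds < 2:
        raise ValueError("n_rounds must be >= 2")
    if motifs is not None and motif_config is not None:
        raise ValueError("pass fixed motif sets or a motif config, not both")
    rounds = []
    for r in range(n_rounds):
        seed = derive_seed(master_seed, r)
        internal, external = split_dataset(main, train_fraction, seed)
        internal_metrics = fivefold_cv(
            internal, spec, config, seed, motifs, motif_config
        )
        round_motifs = motifs
        if motif_config is not None:
            round_motifs = discover_motif_augment(internal, motif_config)
        bundle = train(internal, spec, config, round_motifs, seed=seed)
        ext_peptides = external.all_peptides()
        # score only what the spec can encode; too-short peptides are
        # excluded on both sides consistently
        _, ok, _ = featurize_peptides(ext_peptides, spec, on_short="drop")
        scores = decision_scores(bundle, ok)
        external_metrics = compute_metrics(_labels_to_y(ok), scores, config.threshold)
        rounds.append(BaggingRound(r, seed, internal_metrics, external_metrics))
    return BaggingReport(tuple(rounds))


def tune_hyperparameters(
    internal: PeptideDataset,
    spec: FeatureSpec,
    g_grid: Sequence[float] = (1e-5, 1e-4, 5e-4, 1e-3, 0.01, 0.05, 0.1, 0.5),
    c_grid: Sequence[float] = (1, 2, 3, 6, 9),
    j_grid: Sequence[float] = (1, 2, 3, 4),
    seed: int = 0,
    threshold: float = 0.0,
) -> Tuple[SVMConfig, pd.DataFrame]:
    """Small grid search selecting (g, c, j) by internal fivefold MCC.

    Returns the winning config (at the given threshold) and the full grid
    table for inspection. Ties prefer smaller g, then smaller c, then
    smaller j.
    """
    rows = []
    best = None
    for g in g_grid:
        for c in c_grid:
            for j in j_grid:
                cfg = SVMConfig(g=g, c=c, j=j, threshold=threshold)
                m = fivefold_cv(internal, spec, cfg, seed)
                rows.append({"g": g, "c": c, "j": j, "mcc": m.mcc,
                             "accuracy": m.accuracy, "auroc": m.auroc})
                key = (-round(m.mcc, 12), g, c, j)
                if best is None or key < best[0]:
                    best = (key, cfg)
    return best[1], pd.DataFrame(rows)


def save_bundle(bundle: ModelBundle, path) -> None:
    """Serialize a model bundle (joblib archive with a format version)."""
    joblib.dump(
        {
            "format_version": BUNDLE_FORMAT_VERSION,
            "software_version": __version__,
            "bundle": bundle,
        },
        path,
    )


def load_bundle(path) -> ModelBundle:
    """Load a bundle, checking format version and feature dimensionality."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read model bundle {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not an acep model bundle")
    if payload["format_version"] != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"bundle format version {payload['format_version']} unsupported "
            f"(expected {BUNDLE_FORMAT_VERSION})"
        )
    bundle = payload["bundle"]
    expected = bundle.feature_spec.vector_length
    fitted = int(bundle.estimator.n_features_in_)
    if fitted != expected:
        raise ValueError(
            f"bundle is inconsistent: feature spec declares {expected} features "
            f"but the fitted model expects {fitted}"
        )
    return bundle
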