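import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef
from sklearn.svm import SVC

from acep import SimulationParams, simulate_dataset
from acep.features import FeatureSpec, featurize_peptides
from acep.motif_discovery import Motif, MotifSet, POSITIVE_EXCLUSIVE
from acep.peptide_io import EPITOPE, NON_EPITOPE, Peptide, PeptideDataset
from acep.svm_model import (
    DEFAULT_THRESHOLD_GRID,
    MotifAugment,
    MotifConfig,
    SVMConfig,
    bagging_evaluate,
    classify,
    compute_metrics,
    decision_scores,
    derive_seed,
    discover_motif_augment,
    fivefold_cv,
    load_bundle,
    save_bundle,
    select_threshold,
    split_dataset,
    train,
    _labels_to_y,
)
from conftest import make_peptides


def brute_force_metrics(y, scores, threshold):
    """Oracle: plain-Python confusion counting and textbook formulas."""
    tp = fp = tn = fn = 0
    for yi, si in zip(y, scores):
        pred = 1 if si >= threshold else 0
        if pred == 1 and yi == 1:
            tp += 1
        elif pred == 1 and yi == 0:
            fp += 1
        elif pred == 0 and yi == 0:
            tn += 1
        else:
            fn += 1
    sens = 100 * tp / (tp + fn)
    spec = 100 * tn / (tn + fp)
    acc = 100 * (tp + tn) / len(y)
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if d == 0 else (tp * tn - fp * fn) / math.sqrt(d)
    return tp, fp, tn, fn, sens, spec, acc, mcc


def pairwise_auroc(y, scores):
    """Oracle: Mann-Whitney pairwise comparison with ties counted half."""
    pos = [s for yi, s in zip(y, scores) if yi == 1]
    neg = [s for yi, s in zip(y, scores) if yi == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestSplitDataset:
    def test_published_split_arithmetic(self):
        ds = simulate_dataset(SimulationParams(n_pos=304, n_neg=385, seed=9))
        internal, external = split_dataset(ds, 0.8, seed=0)
        assert (internal.n_pos, internal.n_neg) == (243, 308)
        assert (external.n_pos, external.n_neg) == (61, 77)

    def test_partition_is_disjoint_and_complete(self, small_sim):
        internal, external = split_dataset(small_sim, 0.8, seed=4)
        all_in = {p.sequence for p in internal.all_peptides()}
        all_ex = {p.sequence for p in external.all_peptides()}
        assert all_in.isdisjoint(all_ex)
        assert all_in | all_ex == {p.sequence for p in small_sim.all_peptides()}

    def test_same_seed_same_partition(self, small_sim):
        a = split_dataset(small_sim, 0.8, seed=7)
        b = split_dataset(small_sim, 0.8, seed=7)
        assert [p.id for p in a[0].all_peptides()] == [p.id for p in b[0].all_peptides()]

    def test_half_split_of_ten_per_class(self):
        ds = simulate_dataset(SimulationParams(n_pos=10, n_neg=10, seed=3))
        internal, external = split_dataset(ds, 0.5, seed=1)
        assert (internal.n_pos, internal.n_neg) == (5, 5)
        assert (external.n_pos, external.n_neg) == (5, 5)


class TestComputeMetrics:
    def test_hand_worked_confusion(self):
        y = [1] * 10 + [0] * 10
        scores = [1.0] * 9 + [-1.0] + [-1.0] * 9 + [1.0]
        m = compute_metrics(y, scores, 0.0)
        assert (m.tp, m.fn, m.tn, m.fp) == (9, 1, 9, 1)
        assert m.sensitivity == 90 and m.specificity == 90 and m.accuracy == 90
        assert m.mcc == pytest.approx(0.8)

    def test_perfect_separation(self):
        m = compute_metrics([1, 1, 0, 0], [2.0, 1.0, -1.0, -2.0], 0.0)
        assert m.mcc == 1.0 and m.auroc == 1.0

    def test_single_predicted_class_gives_mcc_zero(self):
        m = compute_metrics([1, 0, 1, 0], [1.0, 1.0, 2.0, 3.0], 0.0)
        assert m.mcc == 0.0

    def test_length_mismatch_and_single_class_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_metrics([1, 0], [1.0], 0.0)
        with pytest.raises(ValueError, match="one class"):
            compute_metrics([1, 1], [1.0, 2.0], 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_and_sklearn_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        y = rng.integers(0, 2, n)
        while y.min() == y.max():
            y = rng.integers(0, 2, n)
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        thr = float(rng.choice(DEFAULT_THRESHOLD_GRID))
        m = compute_metrics(y, scores, thr)
        tp, fp, tn, fn, sens, spec, acc, mcc = brute_force_metrics(y, scores, thr)
        assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)
        assert m.mcc == pytest.approx(mcc)
        assert m.mcc == pytest.approx(
            matthews_corrcoef(y, (scores >= thr).astype(int)), abs=1e-12
        )
        assert m.auroc == pytest.approx(pairwise_auroc(y, scores))

    def test_auroc_negation_symmetry(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 20 + [0] * 20)
        s = rng.normal(size=40)
        a = compute_metrics(y, s, 0.0).auroc
        b = compute_metrics(y, -s, 0.0).auroc
        assert a + b == pytest.approx(1.0)

    def test_threshold_monotonicity_of_sn_sp(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 30 + [0] * 30)
        s = rng.normal(loc=y, size=60)
        sens = [compute_metrics(y, s, t).sensitivity for t in DEFAULT_THRESHOLD_GRID]
        spec = [compute_metrics(y, s, t).specificity for t in DEFAULT_THRESHOLD_GRID]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))


class TestSelectThreshold:
    def test_separable_scores_pick_the_separating_threshold(self):
        assert select_threshold([0, 0, 1, 1], [-1, -1, 1, 1], [-2, 0, 2]) == 0

    def test_total_tie_returns_grid_minimum(self):
        assert select_threshold([0, 1], [0.5, 0.5], [-1, 0, 1]) == -1

    def test_maximizes_mcc_with_sn_sp_tiebreak(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 25 + [0] * 25)
        s = rng.normal(loc=0.8 * y, size=50)
        t = select_threshold(y, s)
        best_mcc = max(compute_metrics(y, s, g).mcc for g in DEFAULT_THRESHOLD_GRID)
        assert compute_metrics(y, s, t).mcc == pytest.approx(best_mcc)


class TestTrainAndScore:
    def test_separable_toy_set_trains_to_perfection(self):
        pos = make_peptides(["RRRRR", "RRRRK", "RRRKK"], EPITOPE, "pos")
        neg = make_peptides(["EEEEE", "EEEEG", "EEEGG"], NON_EPITOPE, "neg")
        ds = PeptideDataset(tuple(pos), tuple(neg))
        bundle = train(ds, FeatureSpec("AAC"), SVMConfig(g=0.001, c=10))
        scores = decision_scores(bundle, ds.all_peptides())
        labels = classify(bundle, ds.all_peptides())
        assert labels == [EPITOPE] * 3 + [NON_EPITOPE] * 3
        assert all(s > 0 for s in scores[:3])

    def test_j_equal_one_matches_unweighted_fit(self, small_sim):
        spec = FeatureSpec("DPC")
        cfg = SVMConfig(g=0.0005, c=1, j=1)
        bundle = train(small_sim, spec, cfg)
        X, ok, _ = featurize_peptides(small_sim.all_peptides(), spec)
        plain = SVC(kernel="rbf", gamma=cfg.g, C=cfg.c).fit(X, _labels_to_y(ok))
        np.testing.assert_allclose(
            bundle.estimator.decision_function(X), plain.decision_function(X)
        )

    def test_hybrid_adds_motif_weight_to_raw_score(self, small_sim, dpc_config):
        pep = small_sim.positives[0]
        motif = MotifSet(
            POSITIVE_EXCLUSIVE, (Motif(pep.sequence[:3], 1, 0),), 1, 3, 8
        )
        plain = train(small_sim, FeatureSpec("DPC"), dpc_config)
        hybrid = train(
            small_sim, FeatureSpec("DPC"), dpc_config,
            MotifAugment(motif, None, 0.5),
        )
        raw = decision_scores(plain, [pep])[0]
        assert decision_scores(hybrid, [pep])[0] == pytest.approx(raw + 0.5)

    def test_empty_peptide_list_scores_empty(self, dpc_bundle):
        assert decision_scores(dpc_bundle, []).size == 0

    def test_score_tie_at_threshold_is_positive(self, small_sim, dpc_bundle):
        pep = small_sim.positives[0]
        s = float(decision_scores(dpc_bundle, [pep])[0])
        at_tie = dpc_bundle.with_threshold(s)
        assert classify(at_tie, [pep]) == [EPITOPE]

    def test_nonstandard_threshold_accepted(self, small_sim):
        cfg = SVMConfig(g=0.0005, c=1, j=1, threshold=-0.2)
        bundle = train(small_sim, FeatureSpec("AAC"), cfg)
        assert bundle.threshold == -0.2


class TestFivefoldCV:
    def test_deterministic_under_seed(self, small_sim, dpc_config):
        a = fivefold_cv(small_sim, FeatureSpec("DPC"), dpc_config, seed=5)
        b = fivefold_cv(small_sim, FeatureSpec("DPC"), dpc_config, seed=5)
        assert a == b

    def test_separable_data_scores_high(self, separable_sim, dpc_config):
        m = fivefold_cv(separable_sim, FeatureSpec("DPC"), dpc_config, seed=5)
        assert m.accuracy >= 95

    def test_class_too_small_rejected(self):
        ds = simulate_dataset(SimulationParams(n_pos=4, n_neg=10, seed=0))
        with pytest.raises(ValueError, match="fivefold"):
            fivefold_cv(ds, FeatureSpec("AAC"), SVMConfig(g=0.01))


class TestBagging:
    def test_default_round_count_and_determinism(self, small_sim, dpc_config):
        a = bagging_evaluate(small_sim, FeatureSpec("AAC"), dpc_config,
                             n_rounds=10, master_seed=7)
        assert len(a.rounds) == 10
        b = bagging_evaluate(small_sim, FeatureSpec("AAC"), dpc_config,
                             n_rounds=10, master_seed=7)
        assert a == b

    def test_summary_recomputable_from_rounds(self, small_sim, dpc_config):
        rep = bagging_evaluate(small_sim, FeatureSpec("AAC"), dpc_config,
                               n_rounds=3, master_seed=1)
        s = rep.summary()
        accs = [r.internal.accuracy for r in rep.rounds]
        row = s[(s["split"] == "internal") & (s["metric"] == "accuracy")]
        assert row["mean"].iloc[0] == pytest.approx(np.mean(accs))
        assert row["sd"].iloc[0] == pytest.approx(np.std(accs, ddof=1))

    def test_derived_seeds_are_small_nonnegative(self):
        seeds = [derive_seed(12345, r) for r in range(10)]
        assert len(set(seeds)) == 10
        assert all(0 <= s < 2**31 for s in seeds)

    def test_motif_protocols_are_exclusive(self, small_sim, dpc_config):
        aug = discover_motif_augment(small_sim, MotifConfig())
        with pytest.raises(ValueError, match="not both"):
            bagging_evaluate(small_sim, FeatureSpec("AAC"), dpc_config,
                             n_rounds=2, master_seed=0,
                             motifs=aug, motif_config=MotifConfig())


class TestBundlePersistence:
    def test_round_trip_preserves_scores(self, tmp_path, small_sim, dpc_bundle):
        path = tmp_path / "model.joblib"
        save_bundle(dpc_bundle, path)
        loaded = load_bundle(path)
        peps = small_sim.all_peptides()[:10]
        np.testing.assert_array_equal(
            decision_scores(dpc_bundle, peps), decision_scores(loaded, peps)
        )
        assert loaded.provenance["seed"] == 11

    def test_corrupted_payload_rejected(self, tmp_path):
        path = tmp_path / "bad.joblib"
        path.write_bytes(b"not a joblib archive")
        with pytest.raises(ValueError):
            load_bundle(path)

    def test_feature_length_mismatch_detected(self, tmp_path, dpc_bundle):
        import dataclasses

        broken = dataclasses.replace(dpc_bundle, feature_spec=FeatureSpec("AAC"))
        path = tmp_path / "broken.joblib"
        save_bundle(broken, path)
        with pytest.raises(ValueError, match="inconsistent"):
            load_bundle(path)
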