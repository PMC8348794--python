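"""Data divisions, network training, ensembling, and evaluation surfaces."""

import numpy as np
import pandas as pd
import pytest

from cogload.classify import (
    NetConfig,
    VotingEnsemble,
    default_grid,
    evaluate,
    feature_matrix,
    grid_search,
    split_data,
    subset_epochs,
    train_ensemble,
    train_once,
    _roc,
)
from cogload.features import feature_columns
from cogload.simulate import LoadEffectProfile

from conftest import cohort_features, condition_features


def toy_features(n_per_class=60, sep=3.0, seed=0, classes=("L0", "L3"), n_subjects=1):
    """Gaussian blobs in the 56-dim feature space, optionally per subject."""
    rng = np.random.default_rng(seed)
    frames = []
    for s in range(n_subjects):
        for day in (1, 2):
            for k, cond in enumerate(classes):
                center = np.zeros(56)
                center[:8] = k * sep
                vals = rng.standard_normal((n_per_class, 56)) + center
                df = pd.DataFrame(vals, columns=feature_columns())
                df.insert(0, "subject", f"S{s + 1:02d}")
                df.insert(1, "day", day)
                df.insert(2, "condition", cond)
                df.insert(3, "is_target", rng.random(n_per_class) < 1 / 3)
                df.insert(4, "responded", rng.random(n_per_class) < 0.9)
                frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestSplitData:
    def test_subject_16_4_4(self):
        df = toy_features(n_per_class=4, n_subjects=24)
        split = split_data(df, "subject_16_4_4", seed=1)
        groups = [set(part["subject"]) for part in split]
        assert [len(g) for g in groups] == [16, 4, 4]
        assert not (groups[0] & groups[1] or groups[0] & groups[2] or groups[1] & groups[2])

    def test_subject_scheme_needs_24(self):
        df = toy_features(n_per_class=4, n_subjects=10)
        with pytest.raises(ValueError, match="24"):
            split_data(df, "subject_16_4_4", seed=1)

    def test_day1_scheme_halves_day2_chronologically(self):
        df = toy_features(n_per_class=10, n_subjects=2)
        split = split_data(df, "day1_train_day2_val_test", seed=0)
        assert set(split.train["day"]) == {1}
        assert set(split.validation["day"]) == set(split.test["day"]) == {2}
        for subj in ("S01", "S02"):
            for cond in ("L0", "L3"):
                va = split.validation.query("subject == @subj and condition == @cond")
                te = split.test.query("subject == @subj and condition == @cond")
                # chronological halves, balanced within each condition
                assert va.index.max() < te.index.min()
                assert abs(len(va) - len(te)) <= 1

    def test_train_1p5_days_partition(self):
        df = toy_features(n_per_class=10, n_subjects=2)
        split = split_data(df, "train_1p5_days", seed=0)
        n = len(df)
        assert len(split.train) + len(split.validation) + len(split.test) == n
        assert len(split.train) == pytest.approx(0.75 * n, abs=4)
        idx = set(split.train.index) | set(split.validation.index) | set(split.test.index)
        assert len(idx) == n  # epoch-level disjointness

    def test_leave_one_out_folds(self):
        df = toy_features(n_per_class=6, n_subjects=8)
        folds = split_data(df, "leave_one_out", seed=2)
        assert len(folds) == 8
        for fold in folds:
            held = fold.fold
            assert set(fold.test["subject"]) == {held}
            assert held not in set(fold.train["subject"]) | set(fold.validation["subject"])
            # validation is ~10% of the pool, stratified by condition
            pool = len(fold.train) + len(fold.validation)
            assert len(fold.validation) == pytest.approx(0.1 * pool, rel=0.3)

    def test_same_seed_same_partition(self):
        df = toy_features(n_per_class=4, n_subjects=24)
        a = split_data(df, "subject_16_4_4", seed=9)
        b = split_data(df, "subject_16_4_4", seed=9)
        assert set(a.test["subject"]) == set(b.test["subject"])
        c = split_data(df, "subject_16_4_4", seed=10)
        assert set(a.test["subject"]) != set(c.test["subject"])

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="scheme"):
            split_data(toy_features(), "bogus", seed=0)


class TestSubsetEpochs:
    def test_all_is_identity(self):
        df = toy_features(n_per_class=10)
        pd.testing.assert_frame_equal(subset_epochs(df, "all"), df)

    def test_target_counts(self):
        df = toy_features(n_per_class=30, seed=4)
        targets = subset_epochs(df, "target")
        assert targets["is_target"].all()
        correct = subset_epochs(df, "correct")
        assert (correct["is_target"] == correct["responded"]).all()
        both = subset_epochs(df, "target+correct")
        assert (both["is_target"] & both["responded"]).all()

    def test_subsample_reproducible(self):
        df = toy_features(n_per_class=30, seed=5)
        a = subset_epochs(df, "nontarget", subsample_to=20, seed=3)
        b = subset_epochs(df, "nontarget", subsample_to=20, seed=3)
        assert len(a) == 20
        pd.testing.assert_frame_equal(a, b)

    def test_empty_result_names_criterion(self):
        df = toy_features(n_per_class=10)
        df["is_target"] = False
        with pytest.raises(ValueError, match="target"):
            subset_epochs(df, "target")


class TestTrainOnce:
    def test_separable_data_reaches_95(self):
        df = toy_features(sep=4.0, seed=6)
        tr = df[df["day"] == 1]
        va = df[df["day"] == 2]
        net = train_once(NetConfig(1, 10), tr, va, seed=0, max_epochs=80)
        assert net.val_accuracy >= 0.95

    def test_shuffled_labels_give_chance(self):
        df = toy_features(sep=4.0, seed=7)
        rng = np.random.default_rng(0)
        df["condition"] = rng.permutation(df["condition"].to_numpy())
        tr = df[df["day"] == 1]
        va = df[df["day"] == 2]
        accs = [
            train_once(NetConfig(1, 10), tr, va, seed=s, max_epochs=40).val_accuracy
            for s in range(5)
        ]
        assert abs(np.mean(accs) - 0.5) < 0.08

    def test_same_seed_identical_weights(self):
        df = toy_features(seed=8)
        tr, va = df[df["day"] == 1], df[df["day"] == 2]
        a = train_once(NetConfig(1, 5), tr, va, seed=3, max_epochs=25)
        b = train_once(NetConfig(1, 5), tr, va, seed=3, max_epochs=25)
        for ca, cb in zip(a.net.coefs_, b.net.coefs_):
            np.testing.assert_array_equal(ca, cb)

    def test_single_class_train_rejected(self):
        df = toy_features(seed=9)
        single = df[df["condition"] == "L0"]
        with pytest.raises(ValueError, match="single class"):
            train_once(NetConfig(1, 5), single, single, seed=0)


class TestGridSearch:
    def test_single_config_returned(self):
        df = toy_features(seed=10)
        tr, va = df[df["day"] == 1], df[df["day"] == 2]
        only = NetConfig(2, 5)
        best, table = grid_search([only], tr, va, repeats=2, seed=0, max_epochs=20)
        assert best == only
        assert len(table) == 1

    def test_tie_breaks_toward_smaller_architecture(self):
        """On cleanly separable data every architecture is perfect; the
        winner must then be the fewest-layers, fewest-nodes config."""
        df = toy_features(sep=6.0, seed=11)
        tr, va = df[df["day"] == 1], df[df["day"] == 2]
        grid = [NetConfig(2, 20), NetConfig(1, 20), NetConfig(1, 5)]
        best, table = grid_search(grid, tr, va, repeats=2, seed=0, max_epochs=40)
        assert (best.n_layers, best.n_nodes) == (1, 5)
        assert table["mean_val_accuracy"].min() >= 0.95

    def test_empty_grid(self):
        with pytest.raises(ValueError, match="empty"):
            grid_search([], toy_features(), toy_features(), repeats=1)

    def test_default_grid_matches_protocol(self):
        grid = default_grid()
        assert len(grid) == 36
        assert {c.n_layers for c in grid} == {1, 2, 3}
        assert {c.n_nodes for c in grid} == {1, 5, 10, 15, 20, 30, 40, 50, 60, 70, 80, 90}


class TestEnsemble:
    def test_single_member_equals_net(self):
        df = toy_features(seed=12)
        tr, va, te = df[df["day"] == 1], df[df["day"] == 2], df[df["day"] == 2]
        ens = train_ensemble(NetConfig(1, 5), tr, va, n_members=1, seed=4, max_epochs=20)
        X, _, _ = feature_matrix(te)
        np.testing.assert_array_equal(ens.predict(X), ens.members[0].predict(X))

    def test_vote_tie_resolved_by_mean_score(self):
        df = toy_features(seed=13)
        tr, va = df[df["day"] == 1], df[df["day"] == 2]
        a = train_once(NetConfig(1, 5), tr, va, seed=1, max_epochs=20)
        b = train_once(NetConfig(1, 5), tr, va, seed=2, max_epochs=20)
        ens = VotingEnsemble(members=[a, b], config=NetConfig(1, 5))
        X, _, _ = feature_matrix(va)
        pred = ens.predict(X)
        pa, pb = a.predict(X), b.predict(X)
        tied = pa != pb
        if tied.any():
            scores = ens.mean_scores(X[tied])
            expect = ens.classes[np.argmax(scores, axis=1)]
            np.testing.assert_array_equal(pred[tied], expect)

    def test_deterministic_given_seed(self):
        df = toy_features(seed=14)
        tr, va = df[df["day"] == 1], df[df["day"] == 2]
        X, _, _ = feature_matrix(va)
        e1 = train_ensemble(NetConfig(1, 5), tr, va, n_members=3, seed=7, max_epochs=15)
        e2 = train_ensemble(NetConfig(1, 5), tr, va, n_members=3, seed=7, max_epochs=15)
        np.testing.assert_array_equal(e1.predict(X), e2.predict(X))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            VotingEnsemble(members=[], config=NetConfig(1, 5))


class TestEvaluate:
    def _trained(self, sep=5.0, seed=15):
        df = toy_features(sep=sep, seed=seed)
        tr, va, te = df[df["day"] == 1], df[df["day"] == 2], df[df["day"] == 2]
        ens = train_ensemble(NetConfig(1, 10), tr, va, n_members=3, seed=1, max_epochs=40)
        return ens, te

    def test_near_perfect_predictions(self):
        ens, te = self._trained()
        rep = evaluate(ens, te, ("L0", "L3"))
        assert rep.accuracy >= 0.98
        assert rep.auc >= 0.99
        assert rep.confusion.sum() == len(te)
        assert np.trace(rep.confusion) >= 0.98 * len(te)
        assert rep.sensitivity >= 0.95 and rep.specificity >= 0.95
        assert rep.recall == rep.sensitivity

    def test_confusion_rows_sum_to_class_counts(self):
        ens, te = self._trained(sep=1.0, seed=16)
        rep = evaluate(ens, te, ("L0", "L3"))
        counts = te["condition"].value_counts()
        np.testing.assert_array_equal(
            rep.confusion.sum(axis=1), [counts["L0"], counts["L3"]]
        )

    def test_missing_class_reported(self):
        ens, te = self._trained()
        rep = evaluate(ens, te[te["condition"] == "L0"], ("L0", "L3"))
        assert rep.missing_classes == ("L3",)
        assert rep.auc is None

    def test_auc_matches_pairwise_concordance_oracle(self):
        """Trapezoidal AUC equals the O(n^2) probability that a positive
        outscores a negative (ties counted half)."""
        rng = np.random.default_rng(17)
        scores = rng.random(200).round(2)  # coarse grid forces ties
        truth = rng.random(200) < 0.4
        _, auc = _roc(scores, truth)
        pos, neg = scores[truth], scores[~truth]
        gt = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert auc == pytest.approx(gt, abs=1e-9)

    def test_random_predictions_near_chance_four_class(self):
        rng = np.random.default_rng(18)
        conf = np.zeros((4, 4), dtype=int)
        for true in range(4):
            pred = rng.integers(0, 4, size=500)
            for p in pred:
                conf[true, p] += 1
        acc = np.trace(conf) / conf.sum()
        assert acc == pytest.approx(0.25, abs=0.03)


def test_split_scheme_ordering_with_subject_variability():
    """With planted subject-level variability, within-session calibration
    beats day-level calibration, which beats the subject-wise division."""
    df = cohort_features(
        24, ["L0", "L3"], 30, seed=24,
        profile=LoadEffectProfile().scaled(0.5),
        subject_sd=0.10, day_sd=0.05, day_gain_sd=0.03,
    )
    accs = {}
    for scheme in ("train_1p5_days", "day1_train_day2_val_test", "subject_16_4_4"):
        runs = []
        for seed in (0, 1, 2, 3):
            split = split_data(df, scheme, seed=seed)
            ens = train_ensemble(
                NetConfig(1, 10), split.train, split.validation,
                n_members=3, seed=seed, max_epochs=40,
            )
            runs.append(evaluate(ens, split.test, ("L0", "L3")).accuracy)
        accs[scheme] = float(np.mean(runs))
    assert accs["train_1p5_days"] >= accs["day1_train_day2_val_test"] - 0.02
    assert accs["day1_train_day2_val_test"] >= accs["subject_16_4_4"] - 0.02
    assert accs["train_1p5_days"] > accs["subject_16_4_4"]
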