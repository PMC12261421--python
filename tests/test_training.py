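"""Homology-aware splits, dataset assembly, schedule and early stopping."""

import numpy as np
import pandas as pd
import pytest

import orgnet as og
from orgnet.training import EarlyStopping, ReduceLROnPlateau


def _brute_force_clusters(mat, threshold):
    """Transitive closure by repeated neighbourhood expansion."""
    n = mat.shape[0]
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        seed = unassigned.pop()
        members = {seed}
        frontier = {seed}
        while frontier:
            nxt = set()
            for i in frontier:
                for j in range(n):
                    if j not in members and mat[i, j] > threshold:
                        nxt.add(j)
            members |= nxt
            unassigned -= nxt
            frontier = nxt
        clusters.append(frozenset(members))
    return set(clusters)


class TestHomologyClusters:
    def test_hand_example(self):
        ids = ["A", "B", "C", "D"]
        mat = np.full((4, 4), 0.0)
        np.fill_diagonal(mat, 100.0)
        mat[0, 1] = mat[1, 0] = 30.0
        mat[1, 2] = mat[2, 1] = 10.0
        mat[2, 3] = mat[3, 2] = 40.0
        df = pd.DataFrame(mat, index=ids, columns=ids)
        clusters = {frozenset(c) for c in og.homology_clusters(df, 25.0)}
        assert clusters == {frozenset({"A", "B"}), frozenset({"C", "D"})}

    def test_all_below_threshold_gives_singletons(self):
        mat = np.full((5, 5), 10.0)
        np.fill_diagonal(mat, 100.0)
        clusters = og.homology_clusters(mat, 25.0)
        assert sorted(len(c) for c in clusters) == [1] * 5

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            raw = rng.uniform(0, 50, size=(8, 8))
            mat = (raw + raw.T) / 2
            np.fill_diagonal(mat, 100.0)
            got = {frozenset(c) for c in og.homology_clusters(mat, 25.0)}
            assert got == _brute_force_clusters(mat, 25.0)

    def test_asymmetric_matrix_rejected(self):
        mat = np.eye(3) * 100
        mat[0, 1] = 30.0
        with pytest.raises(ValueError):
            og.homology_clusters(mat, 25.0)


class TestMakeFolds:
    def test_ten_singletons_two_per_fold(self):
        clusters = [[f"p{i}"] for i in range(10)]
        split = og.make_folds(clusters, k=5, seed=0)
        for train, val in split.folds:
            assert len(val) == 2
            assert len(train) == 8
            assert set(train) | set(val) == set(range(10))
            assert not set(train) & set(val)

    def test_deterministic_given_seed(self):
        clusters = [[f"p{i}"] for i in range(10)]
        a = og.make_folds(clusters, k=5, seed=3)
        b = og.make_folds(clusters, k=5, seed=3)
        for (t1, v1), (t2, v2) in zip(a.folds, b.folds):
            np.testing.assert_array_equal(v1, v2)

    def test_no_cluster_straddles_train_and_validation(self):
        rng = np.random.default_rng(1)
        for trial in range(100):
            n_clusters = int(rng.integers(5, 12))
            clusters = []
            pid = 0
            for c in range(n_clusters):
                size = int(rng.integers(1, 4))
                clusters.append([f"p{pid + i}" for i in range(size)])
                pid += size
            groups = [p for cl in clusters for p in cl for _ in range(2)]
            split = og.make_folds(clusters, k=5, seed=trial, record_groups=groups)
            cluster_of = {p: ci for ci, cl in enumerate(clusters) for p in cl}
            for train, val in split.folds:
                tc = {cluster_of[groups[i]] for i in train}
                vc = {cluster_of[groups[i]] for i in val}
                assert not tc & vc

    def test_fewer_clusters_than_folds_rejected(self):
        with pytest.raises(ValueError):
            og.make_folds([["a"], ["b"]], k=5, seed=0)


@pytest.fixture(scope="module")
def assembled(small_dataset):
    pairs = og.featurize_dataset(small_dataset)
    return og.assemble_dataset(
        small_dataset.records, pairs, mode="wt_diff", augment_reverse=True
    ), small_dataset


@pytest.fixture(scope="module")
def tiny(small_dataset):
    pairs = og.featurize_dataset(small_dataset)
    tds = og.assemble_dataset(
        small_dataset.records, pairs, mode="wt_diff", augment_reverse=True
    )
    idx = np.arange(len(tds))
    return tds, (idx[:12], idx[12:])


class TestAssembleDataset:
    def test_reverse_augmentation_doubles(self, assembled):
        tds, ds = assembled
        assert len(tds) == 2 * len(ds.records)

    def test_label_sign_symmetry(self, assembled):
        tds, _ = assembled
        assert tds.y.mean() == pytest.approx(0.0, abs=1e-9)

    def test_pairs_share_fold(self, assembled):
        tds, ds = assembled
        clusters = og.homology_clusters(ds.identity, 25.0)
        split = og.make_folds(clusters, k=3, seed=0, record_groups=tds.groups)
        for train, val in split.folds:
            for idx_set in (set(train), set(val)):
                for pid in np.unique(tds.pair_ids):
                    members = set(np.flatnonzero(tds.pair_ids == pid))
                    assert members <= idx_set or not (members & idx_set)

    def test_reverse_item_is_swapped_and_negated(self, assembled):
        tds, _ = assembled
        direct, reverse = tds.X[0], tds.X[1]
        assert tds.y[1] == pytest.approx(-tds.y[0], abs=1e-9)
        np.testing.assert_allclose(
            reverse[..., 7:], -direct[..., 7:], atol=1e-6
        )

    def test_missing_representation_skipped_and_listed(self, small_dataset):
        pairs = og.featurize_dataset(small_dataset)
        pairs[2] = None
        tds = og.assemble_dataset(
            small_dataset.records, pairs, mode="wt_diff", augment_reverse=False
        )
        assert len(tds) == len(small_dataset.records) - 1
        assert len(tds.failures) == 1
        assert tds.failures[0][0] == small_dataset.records[2]


class TestSchedule:
    def test_lr_halves_after_ten_stalled_epochs(self):
        sched = ReduceLROnPlateau(lr=1e-3, factor=0.5, patience=10, cooldown=5)
        sched.step(1.0)  # establishes the best
        for _ in range(9):
            assert sched.step(1.0) == pytest.approx(1e-3)
        assert sched.step(1.0) == pytest.approx(5e-4)

    def test_cooldown_defers_next_reduction(self):
        sched = ReduceLROnPlateau(lr=1e-3, factor=0.5, patience=2, cooldown=3)
        sched.step(1.0)
        sched.step(1.0)
        assert sched.step(1.0) == pytest.approx(5e-4)  # first reduction
        # cooldown epochs do not count toward patience
        for _ in range(3):
            assert sched.step(1.0) == pytest.approx(5e-4)
        assert sched.step(1.0) == pytest.approx(5e-4)
        assert sched.step(1.0) == pytest.approx(2.5e-4)

    def test_improvement_resets_counter(self):
        sched = ReduceLROnPlateau(lr=1e-3, factor=0.5, patience=3, cooldown=0)
        sched.step(1.0)
        sched.step(1.0)
        sched.step(0.5)  # improvement
        for _ in range(2):
            assert sched.step(0.5) == pytest.approx(1e-3)
        assert sched.step(0.5) == pytest.approx(5e-4)

    def test_early_stop_fires_at_patience(self):
        stopper = EarlyStopping(patience=15)
        assert not stopper.step(1.0)
        fired_at = None
        for epoch in range(2, 20):
            if stopper.step(1.0):
                fired_at = epoch
                break
        assert fired_at == 16  # patience + 1 with a frozen validation loss


class TestTrainFold:
    def test_loss_decreases_on_learnable_data(self, tiny):
        tds, fold = tiny
        model = og.build_thermonet_like(og.ModelConfig("thermonet_like", 14), seed=0)
        cfg = og.TrainConfig(epochs=8, seed=0)
        _, hist = og.train_fold(model, tds, fold, cfg)
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_bit_reproducible_with_fixed_seed(self, tiny):
        tds, fold = tiny
        hists = []
        for _ in range(2):
            model = og.build_thermonet_like(og.ModelConfig("thermonet_like", 14), seed=2)
            _, hist = og.train_fold(model, tds, fold, og.TrainConfig(epochs=3, seed=2))
            hists.append(hist)
        assert hists[0]["train_loss"] == hists[1]["train_loss"]
        assert hists[0]["val_loss"] == hists[1]["val_loss"]

    def test_early_stop_on_constructed_stall(self, tiny):
        """With lr = min_lr ≈ 0 nothing changes, so validation stalls and
        training stops at patience + 1 epochs."""
        tds, fold = tiny
        model = og.build_thermonet_like(og.ModelConfig("thermonet_like", 14), seed=1)
        cfg = og.TrainConfig(
            epochs=30, seed=1, lr=1e-300, min_lr=1e-300, early_stop_patience=4
        )
        _, hist = og.train_fold(model, tds, fold, cfg)
        assert len(hist["val_loss"]) == cfg.early_stop_patience + 1

    def test_empty_training_fold_rejected(self, tiny):
        tds, _ = tiny
        model = og.build_thermonet_like(og.ModelConfig("thermonet_like", 14), seed=0)
        with pytest.raises(ValueError):
            og.train_fold(
                model, tds, (np.array([], dtype=int), np.arange(4)), og.TrainConfig()
            )

    def test_classification_mode_excludes_zero_ddg(self, tiny):
        tds, fold = tiny
        model = og.build_thermonet_like(
            og.ModelConfig("thermonet_like", 14, head="classification"), seed=0
        )
        cfg = og.TrainConfig(epochs=2, seed=0, loss="bce")
        _, hist = og.train_fold(model, tds, fold, cfg)
        assert len(hist["train_loss"]) == 2
        assert all(np.isfinite(v) for v in hist["train_loss"])


def test_ensemble_mse_never_exceeds_mean_member_mse(tiny):
    """Averaging predictions cannot hurt MSE on shared targets (convexity)."""
    tds, fold = tiny
    _, val_idx = fold
    X = tds.X[val_idx].astype(float)
    y = tds.y[val_idx]
    models = [
        og.build_thermonet_like(og.ModelConfig("thermonet_like", 14), seed=s)
        for s in (1, 2, 3)
    ]
    member_preds = [og.predict(m, X) for m in models]
    member_mses = [np.mean((p - y) ** 2) for p in member_preds]
    ensemble_mse = np.mean((np.mean(member_preds, axis=0) - y) ** 2)
    assert ensemble_mse <= np.mean(member_mses) + 1e-6


def test_train_ensemble_one_model_per_fold(small_dataset):
    pairs = og.featurize_dataset(small_dataset)
    tds = og.assemble_dataset(
        small_dataset.records, pairs, mode="wt_diff", augment_reverse=True
    )
    clusters = og.homology_clusters(small_dataset.identity, 25.0)
    split = og.make_folds(clusters, k=3, seed=0, record_groups=tds.groups)
    builder = lambda seed: og.build_thermonet_like(
        og.ModelConfig("thermonet_like", 14), seed
    )
    models, manifest = og.train_ensemble(
        tds, split, og.TrainConfig(epochs=2, seed=0), builder
    )
    assert len(models) == 3 and len(manifest) == 3
    for entry in manifest:
        assert np.isfinite(entry["best_val_loss"])
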