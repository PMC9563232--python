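"""1D-CNN architecture contract, training behavior, signal extraction, VOS rule."""

import numpy as np
import pandas as pd
import pytest

from natfmri.temporal_cnn import (
    build_cnn,
    CNNSpec,
    extract_voxel_signals,
    identify_vos,
    layer_lengths,
    train_eval_loocv,
    VoxelPredictionTable,
    zscore_signals,
)


class TestArchitecture:
    def test_layer_lengths_for_60_volume_input(self):
        assert layer_lengths(60) == [60, 30, 15, 7, 3]
        net = build_cnn(CNNSpec(), 60)
        assert net.dense_in == 8 * 3 == 24

    def test_parameter_counts(self):
        net = build_cnn(CNNSpec(), 60)
        counts = net.parameter_counts()
        assert counts["conv1"] == 7 * 1 * 40 + 40 == 320
        assert counts["conv2"] == 7 * 40 * 32 + 32
        assert counts["dense"] == 24 * 2 + 2

    def test_softmax_head_normalized(self, rng):
        net = build_cnn(CNNSpec(seed=1), 60)
        probs = net.predict_proba(rng.normal(size=(5, 60)))
        assert probs.shape == (5, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            build_cnn(CNNSpec(), 15)

    def test_forward_deterministic_given_seed(self, rng):
        x = rng.normal(size=(4, 60))
        p1 = build_cnn(CNNSpec(seed=9), 60).predict_proba(x)
        p2 = build_cnn(CNNSpec(seed=9), 60).predict_proba(x)
        assert np.array_equal(p1, p2)


class TestTraining:
    @staticmethod
    def _toy_set(n=150, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(60) * 1.5
        X = np.concatenate([
            np.sin(2 * np.pi * 0.06 * t) + 0.4 * rng.normal(size=(n, 60)),
            np.sin(2 * np.pi * 0.25 * t) + 0.4 * rng.normal(size=(n, 60)),
        ])
        y = np.repeat([0, 1], n)
        return X.astype(np.float32), y

    def test_loss_decreases_and_separable_set_learned(self):
        X, y = self._toy_set()
        net = build_cnn(CNNSpec(learning_rate=0.05, epochs=12, seed=2), 60)
        history = net.fit(X, y)
        assert history[-1] < history[0]
        assert np.mean(net.predict(X) == y) >= 0.95

    def test_gradient_descends_analytic_loss(self):
        """A single SGD step on one batch lowers that batch's loss."""
        X, y = self._toy_set(n=32)
        net = build_cnn(CNNSpec(learning_rate=0.01, seed=4), 60)
        onehot = np.eye(2, dtype=np.float32)[y]
        l0 = net.train_step(X, onehot)
        l1 = net.train_step(X, onehot)
        assert l1 < l0


class TestSignalExtraction:
    def test_signal_set_shape_and_labels(self, small_dataset):
        cfg, atlas, mask, truth, runs = small_dataset
        rid = next(iter(truth.spatial_regions))
        sig = extract_voxel_signals(runs, atlas, rid, mask)
        n_region = int(((atlas.labels == rid) & mask).sum())
        assert sig.signals.shape == (n_region, cfg.n_runs, cfg.n_volumes)
        for cat in cfg.categories:
            assert np.sum(sig.categories == cat) == cfg.n_runs // 2

    def test_mask_takes_precedence_over_region_label(self, small_dataset):
        cfg, atlas, mask, truth, runs = small_dataset
        rid = next(iter(truth.spatial_regions))
        tight = mask.copy()
        region_coords = np.argwhere((atlas.labels == rid) & mask)
        excluded = tuple(region_coords[0])
        tight[excluded] = False
        sig = extract_voxel_signals(runs, atlas, rid, tight)
        assert not any(tuple(c) == excluded for c in sig.coords)

    def test_empty_region_rejected(self, small_dataset):
        cfg, atlas, mask, truth, runs = small_dataset
        with pytest.raises(ValueError, match="no in-mask voxels"):
            extract_voxel_signals(runs, atlas, 999, mask)

    def test_constant_series_z_normalizes_to_zeros(self):
        sig = np.ones((2, 3, 10))
        assert np.array_equal(zscore_signals(sig), np.zeros_like(sig))


def _table_from_props(correct_counts, n_excerpts):
    records = []
    for v, k in enumerate(correct_counts):
        flags = [True] * k + [False] * (n_excerpts - k)
        for e, ok in enumerate(flags):
            records.append(
                {"voxel_index": v, "x": v, "y": 0, "z": 0, "excerpt_index": e,
                 "true": "CLA", "pred": "CLA" if ok else "SPE", "correct": ok}
            )
    return VoxelPredictionTable(
        table=pd.DataFrame.from_records(records),
        coords=np.array([[v, 0, 0] for v in range(len(correct_counts))]),
        region_id=1,
        classes=("CLA", "SPE"),
    )


class TestVOS:
    def test_threshold_boundary_at_98_excerpts(self):
        table = _table_from_props([60, 58], 98)
        vos, prop = identify_vos(table, threshold=0.60)
        assert list(vos) == [0]  # 60/98 = 0.612 in; 58/98 = 0.592 out
        assert prop == 0.5

    def test_region_proportion_arithmetic(self):
        table = _table_from_props([90] * 40 + [10] * 24, 98)
        vos, prop = identify_vos(table)
        assert prop == pytest.approx(40 / 64)

    def test_lowering_threshold_never_shrinks_vos(self):
        table = _table_from_props(list(range(0, 99, 7)), 98)
        sizes = [len(identify_vos(table, thr)[0]) for thr in (0.9, 0.6, 0.3, 0.1)]
        assert sizes == sorted(sizes)

    def test_invalid_threshold_rejected(self):
        table = _table_from_props([5], 10)
        with pytest.raises(ValueError, match="threshold"):
            identify_vos(table, threshold=0.0)
        with pytest.raises(ValueError, match="threshold"):
            identify_vos(table, threshold=1.5)


class TestLOOCV:
    @staticmethod
    def _tiny_signals(seed=0):
        """8 voxels x 12 excerpts; half the voxels carry class frequencies."""
        rng = np.random.default_rng(seed)
        t = np.arange(60) * 1.5
        cats = np.array(["CLA", "SPE"] * 6)
        freqs = {"CLA": 0.06, "SPE": 0.25}
        signals = rng.normal(0, 0.4, size=(8, 12, 60))
        for v in range(4):
            for e, cat in enumerate(cats):
                signals[v, e] += 2.0 * np.sin(2 * np.pi * freqs[cat] * t)
        from natfmri.temporal_cnn import VoxelSignalSet, zscore_signals

        return VoxelSignalSet(
            signals=zscore_signals(signals).astype(np.float32),
            coords=np.array([[v, 0, 0] for v in range(8)]),
            categories=cats,
            subjects=np.repeat(np.arange(6), 2),
            excerpt_ids=np.arange(12),
            region_id=1,
        )

    def test_signature_voxels_recovered_and_reproducible(self):
        signals = self._tiny_signals()
        spec = CNNSpec(learning_rate=0.05, epochs=6, seed=8)
        res1 = train_eval_loocv(signals, spec)
        prop = res1.correct_proportion()
        # every signature voxel clears the VOS threshold with margin
        assert prop.iloc[:4].min() >= 0.75
        # identical rerun: the determinism contract
        res2 = train_eval_loocv(signals, spec)
        pd.testing.assert_frame_equal(res1.table, res2.table)
        # every voxel has exactly one record per excerpt
        counts = res1.table.groupby("voxel_index")["excerpt_index"].count()
        assert (counts == 12).all()

    def test_single_class_signals_rejected(self):
        signals = self._tiny_signals()
        signals.categories[:] = "CLA"
        with pytest.raises(ValueError, match="2 categories"):
            train_eval_loocv(signals, CNNSpec(epochs=1))
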