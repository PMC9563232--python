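"""Per-voxel 1D-CNN classification of BOLD time series and VOS identification.

The network is a five-layer 1D convolutional classifier: filter counts
(40, 32, 24, 16, 8), kernel size 7, stride 1, same padding, ReLU activations,
max-pooling of size 2 after each of the last four convolutional layers, and a
2-unit softmax dense head trained with cross-entropy and plain SGD. For a
length-60 input the per-layer feature-map lengths are (60, 30, 15, 7, 3)
(odd lengths pool with floor), so the dense layer sees 8 x 3 = 24 inputs.

Training/evaluation is leave-one-excerpt-out per region: all voxels' signals
from the remaining excerpts form the training set (one shared model per fold),
and the held-out excerpt's signal of each voxel is predicted individually.
Voxels whose held-out predictions are correct in at least 60% of folds are
voxels of significance (VOS).

The network is implemented directly on numpy (im2col convolutions lowered to
BLAS matrix products, hand-written backpropagation); weights are stored as
plain arrays so the kernel-analysis stage can read them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import Atlas, Volume4D


@dataclass(frozen=True)
class CNNSpec:
    filters: tuple[int, ...] = (40, 32, 24, 16, 8)
    kernel_size: int = 7
    pool_size: int = 2
    n_classes: int = 2
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 50
    early_stop_patience: int = 5
    early_stop_min_delta: float = 1e-4
    seed: int = 0


def layer_lengths(input_length: int, spec: CNNSpec = CNNSpec()) -> list[int]:
    """Feature-map length after each convolutional layer (post-pooling)."""
    lengths = []
    L = input_length
    for i in range(len(spec.filters)):
        # same padding, stride 1: conv preserves length
        if i >= 1:
            L = L // spec.pool_size
        lengths.append(L)
    return lengths


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Conv1DNet:
    """The five-conv-layer 1D-CNN with a softmax dense head."""

    def __init__(self, spec: CNNSpec, input_length: int, rng=None):
        if input_length < 2 ** (len(spec.filters) - 1):
            raise ValueError(
                f"input length {input_length} too short: four halvings collapse "
                "the feature map"
            )
        self.spec = spec
        self.input_length = input_length
        self.lengths = layer_lengths(input_length, spec)
        rng = np.random.default_rng(spec.seed) if rng is None else rng

        self.conv_W: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        c_in = 1
        for f in spec.filters:
            # He initialization for ReLU layers
            std = np.sqrt(2.0 / (c_in * spec.kernel_size))
            self.conv_W.append(
                rng.normal(0.0, std, size=(f, c_in, spec.kernel_size)).astype(np.float32)
            )
            self.conv_b.append(np.zeros(f, dtype=np.float32))
            c_in = f
        self.dense_in = spec.filters[-1] * self.lengths[-1]
        std = np.sqrt(2.0 / self.dense_in)
        self.dense_W = rng.normal(0.0, std, size=(spec.n_classes, self.dense_in)).astype(
            np.float32
        )
        self.dense_b = np.zeros(spec.n_classes, dtype=np.float32)

    # -- shape/parameter contracts -------------------------------------------

    def parameter_counts(self) -> dict[str, int]:
        counts = {
            f"conv{i + 1}": int(W.size + b.size)
            for i, (W, b) in enumerate(zip(self.conv_W, self.conv_b))
        }
        counts["dense"] = int(self.dense_W.size + self.dense_b.size)
        return counts

    # -- forward / backward ---------------------------------------------------

    def _conv_forward(self, x, W, b):
        """x: (B, C, L) -> (B, F, L) with same padding, stride 1 (via im2col)."""
        B, C, L = x.shape
        F, _, K = W.shape
        pad = K // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        win = np.lib.stride_tricks.sliding_window_view(xpad, K, axis=2)  # (B,C,L,K)
        cols = win.transpose(0, 2, 1, 3).reshape(B * L, C * K)
        out = cols @ W.reshape(F, C * K).T + b
        return out.reshape(B, L, F).transpose(0, 2, 1), cols

    def _conv_backward(self, dz, cols, W, x_shape):
        """dz: (B, F, L) -> gradients (dW, db, dx)."""
        B, C, L = x_shape
        F, _, K = W.shape
        pad = K // 2
        dz2 = dz.transpose(0, 2, 1).reshape(B * L, F)
        dW = (dz2.T @ cols).reshape(F, C, K)
        db = dz2.sum(axis=0)
        dcols = (dz2 @ W.reshape(F, C * K)).reshape(B, L, C, K)
        dxpad = np.zeros((B, C, L + 2 * pad), dtype=dz.dtype)
        for k in range(K):
            dxpad[:, :, k : k + L] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dW, db, dxpad[:, :, pad : pad + L]

    def forward(self, x: np.ndarray, train: bool = False):
        """x: (B, L) -> class probabilities (B, n_classes)."""
        x = np.ascontiguousarray(x, dtype=np.float32)[:, None, :]  # (B, 1, L)
        cache = [] if train else None
        a = x
        for i, (W, b) in enumerate(zip(self.conv_W, self.conv_b)):
            x_in = a
            z, cols = self._conv_forward(x_in, W, b)
            a = _relu(z)
            pool_idx = None
            pre_pool_len = a.shape[2]
            if i >= 1:
                P = self.spec.pool_size
                L2 = (pre_pool_len // P) * P
                r = a[:, :, :L2].reshape(a.shape[0], a.shape[1], L2 // P, P)
                pool_idx = r.argmax(axis=3)
                a = r.max(axis=3)
            if train:
                cache.append((x_in.shape, cols, z, pool_idx, pre_pool_len))
        flat = a.reshape(a.shape[0], -1)
        logits = flat @ self.dense_W.T + self.dense_b
        probs = _softmax(logits)
        if train:
            return probs, (cache, flat, a.shape)
        return probs

    def train_step(
        self, x: np.ndarray, y_onehot: np.ndarray, sample_weight: np.ndarray | None = None
    ) -> float:
        """One SGD step on a mini-batch; returns the batch cross-entropy."""
        B = x.shape[0]
        probs, (cache, flat, a_shape) = self.forward(x, train=True)
        ce = -np.sum(y_onehot * np.log(probs + 1e-12), axis=1)
        if sample_weight is None:
            loss = float(np.mean(ce))
            dlogits = (probs - y_onehot).astype(np.float32) / B
        else:
            w = sample_weight.astype(np.float32)
            loss = float(np.mean(w * ce))
            dlogits = w[:, None] * (probs - y_onehot).astype(np.float32) / B
        dWd = dlogits.T @ flat
        dbd = dlogits.sum(axis=0)
        da = (dlogits @ self.dense_W).reshape(a_shape)

        grads = []
        for i in range(len(self.conv_W) - 1, -1, -1):
            x_shape, cols, z, pool_idx, pre_pool_len = cache[i]
            if pool_idx is not None:
                P = self.spec.pool_size
                Bc, F, Lp = da.shape
                dup = np.zeros((Bc, F, pre_pool_len), dtype=da.dtype)
                b_ix, f_ix, p_ix = np.meshgrid(
                    np.arange(Bc), np.arange(F), np.arange(Lp), indexing="ij"
                )
                dup[b_ix, f_ix, p_ix * P + pool_idx] = da
                da = dup
            dz = da * (z > 0)
            dW, db, da = self._conv_backward(dz, cols, self.conv_W[i], x_shape)
            grads.append((dW, db))
        grads.reverse()

        lr = self.spec.learning_rate
        for i, (dW, db) in enumerate(grads):
            self.conv_W[i] -= lr * dW
            self.conv_b[i] -= lr * db
        self.dense_W -= lr * dWd
        self.dense_b -= lr * dbd
        return loss

    def fit(
        self, X: np.ndarray, y: np.ndarray, rng=None, balanced: bool = True
    ) -> list[float]:
        """Mini-batch SGD with early stopping on a training-loss plateau.

        ``y`` holds integer class indices. With ``balanced=True`` (default)
        samples are weighted inversely to their class frequency, so a
        leave-one-out fold's slight class imbalance does not bias the
        classifier toward the majority training class. Returns the per-epoch
        mean loss.
        """
        spec = self.spec
        rng = np.random.default_rng(spec.seed) if rng is None else rng
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        onehot = np.eye(spec.n_classes, dtype=np.float32)[y]
        n = len(X)
        weights = None
        if balanced:
            counts = np.bincount(y, minlength=spec.n_classes).astype(float)
            weights = (n / (spec.n_classes * counts[y])).astype(np.float32)
        history: list[float] = []
        best = np.inf
        stale = 0
        for _ in range(spec.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                losses.append(
                    self.train_step(
                        X[idx], onehot[idx],
                        None if weights is None else weights[idx],
                    )
                )
            epoch_loss = float(np.mean(losses))
            history.append(epoch_loss)
            if epoch_loss < best - spec.early_stop_min_delta:
                best = epoch_loss
                stale = 0
            else:
                stale += 1
                if stale >= spec.early_stop_patience:
                    break
        return history

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(X, dtype=np.float32))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def build_cnn(spec: CNNSpec, input_length: int = 60) -> Conv1DNet:
    """Construct the network, validating the architecture contract."""
    return Conv1DNet(spec, input_length)


# ---------------------------------------------------------------------------
# Voxel signal extraction and leave-one-excerpt-out evaluation
# ---------------------------------------------------------------------------


@dataclass
class VoxelSignalSet:
    """Per-voxel time series for every excerpt of one region."""

    signals: np.ndarray  # (n_voxels, n_excerpts, n_volumes)
    coords: np.ndarray  # (n_voxels, 3)
    categories: np.ndarray  # (n_excerpts,)
    subjects: np.ndarray
    excerpt_ids: np.ndarray
    region_id: int

    @property
    def n_voxels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_excerpts(self) -> int:
        return self.signals.shape[1]


def zscore_signals(signals: np.ndarray) -> np.ndarray:
    """Per-signal z-normalization along the last axis; constant signals -> zeros."""
    mean = signals.mean(axis=-1, keepdims=True)
    sd = signals.std(axis=-1, keepdims=True)
    out = np.where(sd > 0, (signals - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def extract_voxel_signals(
    runs: list[Volume4D],
    atlas: Atlas,
    region_id: int,
    mask: np.ndarray,
    normalize: bool = True,
) -> VoxelSignalSet:
    """Extract each in-mask voxel's series from every run for one region.

    Each run is one excerpt presentation. The brain mask takes precedence over
    the region label: voxels outside the mask are excluded. Signals are
    per-series z-normalized by default (raw-intensity mode via normalize=False).
    """
    region = (atlas.labels == region_id) & np.asarray(mask, bool)
    coords = np.argwhere(region)
    if len(coords) == 0:
        raise ValueError(f"region {region_id} has no in-mask voxels")
    sig = np.stack(
        [run.data[:, region].T for run in runs], axis=1
    )  # (n_voxels, n_runs, T)
    if normalize:
        sig = zscore_signals(sig)
    return VoxelSignalSet(
        signals=sig.astype(np.float32),
        coords=coords,
        categories=np.asarray([r.category for r in runs]),
        subjects=np.asarray([r.subject_id for r in runs]),
        excerpt_ids=np.asarray([r.excerpt_id for r in runs]),
        region_id=region_id,
    )


@dataclass
class VoxelPredictionTable:
    """Per-(voxel, held-out excerpt) CNN predictions for one region."""

    table: pd.DataFrame  # voxel_index, excerpt_index, true, pred, correct
    coords: np.ndarray
    region_id: int
    classes: tuple
    models: list = field(default_factory=list, repr=False)

    def correct_proportion(self) -> pd.Series:
        """Fraction of held-out excerpts classified correctly, per voxel."""
        return self.table.groupby("voxel_index")["correct"].mean()


def train_eval_loocv(
    signals: VoxelSignalSet,
    spec: CNNSpec = CNNSpec(),
    keep_models: bool = False,
) -> VoxelPredictionTable:
    """Leave-one-excerpt-out training/evaluation of the region's shared CNN.

    For each held-out excerpt, one model is trained on the pooled signals of
    all the region's voxels over the remaining excerpts and then predicts the
    held-out signal of every voxel. Deterministic for a fixed ``spec.seed``.
    """
    classes = tuple(np.unique(signals.categories))
    if len(classes) != 2:
        raise ValueError("exactly 2 categories required")
    y_all = np.searchsorted(np.asarray(classes), signals.categories)
    n_vox, n_exc, T = signals.signals.shape
    for c in range(2):
        if np.sum(y_all == c) < 2:
            raise ValueError("need >= 2 excerpts per class for leave-one-out folds")

    records = []
    models = []
    for e in range(n_exc):
        train_mask = np.arange(n_exc) != e
        if len(np.unique(y_all[train_mask])) < 2:
            raise ValueError(f"training fold {e} is missing a class")
        X_train = signals.signals[:, train_mask].reshape(-1, T)
        y_train = np.broadcast_to(y_all[train_mask], (n_vox, n_exc - 1)).reshape(-1)

        fold_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, e]))
        model = Conv1DNet(spec, T, rng=fold_rng)
        model.fit(X_train, y_train, rng=fold_rng)

        pred = model.predict(signals.signals[:, e])
        records.extend(
            {
                "voxel_index": v,
                "x": int(signals.coords[v, 0]),
                "y": int(signals.coords[v, 1]),
                "z": int(signals.coords[v, 2]),
                "excerpt_index": e,
                "true": classes[y_all[e]],
                "pred": classes[pred[v]],
                "correct": bool(pred[v] == y_all[e]),
            }
            for v in range(n_vox)
        )
        if keep_models:
            models.append(model)
    return VoxelPredictionTable(
        table=pd.DataFrame.from_records(records),
        coords=signals.coords,
        region_id=signals.region_id,
        classes=classes,
        models=models,
    )


def identify_vos(
    table: VoxelPredictionTable, threshold: float = 0.60
) -> tuple[np.ndarray, float]:
    """Voxels of significance: correct-proportion >= threshold.

    Returns (vos voxel indices, region VOS proportion = |VOS| / n_region_voxels).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    prop = table.correct_proportion()
    vos = prop.index[prop.values >= threshold].to_numpy()
    return vos, len(vos) / len(prop)
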