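"""Frequency-domain interpretation of final-layer convolution kernels.

Each of the 8 last-layer kernels feeds 3 feature-map positions into the 2-unit
dense head, so summing the dense weights over those positions yields a pair of
weights per kernel; the larger one assigns the kernel to a category. The
kernel's taps (length 7, averaged over input channels) are transformed to the
frequency domain, keeping the three non-DC magnitudes X(1..3). The sign
pattern of X(n) - mean(X) classifies the spectrum into six shape types:

    (+,-,-) -> L   low-frequency        (-,-,+) -> L'  high-frequency
    (+,-,+) -> V   mixed                (-,+,-) -> V'  mixed
    (-,+,+) -> G   high-frequency       (+,+,-) -> G'  low-frequency

("G" renders the Greek Gamma.) The deviations from the mean sum to zero, so
the all-above and all-below patterns are infeasible and the six patterns plus
a near-flat class partition every 3-point spectrum. Per (region, category),
the ratios n_G / n_G' and n_L' / n_L measure how much high- relative to
low-frequency structure the learned kernels carry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .temporal_cnn import Conv1DNet

logger = logging.getLogger(__name__)

SHAPE_LABELS = ("L", "L'", "V", "V'", "G", "G'", "flat")

#: sign pattern of X(n) - mean(X) (True = above mean) -> shape label
_PATTERN_TO_SHAPE = {
    (True, False, False): "L",
    (False, False, True): "L'",
    (True, False, True): "V",
    (False, True, False): "V'",
    (False, True, True): "G",
    (True, True, False): "G'",
}

#: shapes counted as high- vs low-frequency in the ratio analysis
HIGH_SHAPES = ("L'", "G")
LOW_SHAPES = ("L", "G'")


@dataclass
class KernelReport:
    kernel_index: int
    class_weights: dict  # category -> aggregated dense weight
    assigned_class: str | None  # None on a tie
    spectrum: np.ndarray  # X(1..3) magnitudes
    shape: str


def map_kernels_to_class(model: Conv1DNet, class_names: tuple) -> list[dict]:
    """Assign each final-layer kernel to the category with the larger
    aggregated dense weight.

    The dense weight matrix is (n_classes, n_kernels * n_positions) with the
    flatten order (kernel, position); weights are summed over each kernel's
    positions. Exactly equal aggregates leave the kernel unassigned (logged).
    """
    if model.dense_W.shape[0] != 2 or len(class_names) != 2:
        raise ValueError("kernel-to-class mapping requires a 2-unit dense head")
    n_kernels = model.spec.filters[-1]
    n_pos = model.lengths[-1]
    W = np.asarray(model.dense_W, dtype=float).reshape(2, n_kernels, n_pos)
    agg = W.sum(axis=2)  # (2, n_kernels)
    out = []
    for k in range(n_kernels):
        weights = {class_names[c]: float(agg[c, k]) for c in range(2)}
        if agg[0, k] == agg[1, k]:
            logger.warning("kernel %d has exactly tied class weights; unassigned", k)
            assigned = None
        else:
            assigned = class_names[int(np.argmax(agg[:, k]))]
        out.append(
            {"kernel_index": k, "class_weights": weights, "assigned_class": assigned}
        )
    return out


def kernel_spectrum(kernel_weights: np.ndarray) -> np.ndarray:
    """Three-point non-DC magnitude spectrum of a length-7 kernel.

    Multichannel kernels (channels x 7) are averaged over input channels
    first. Returns |DFT| at frequency indices 1, 2, 3 — for a length-7 real
    signal these are the only independent oscillatory frequencies (about half
    the kernel size); X(1) is the lowest, X(3) the highest.
    """
    w = np.asarray(kernel_weights, dtype=float)
    if w.ndim == 2:
        w = w.mean(axis=0)
    if w.ndim != 1 or w.shape[0] != 7:
        raise ValueError("kernel must have length 7 (optionally channels x 7)")
    return np.abs(np.fft.fft(w))[1:4]


def classify_shape(
    spectrum: np.ndarray, eps_rel: float = 1e-8, eps_abs: float = 1e-12
) -> str:
    """Shape label from the sign pattern of X(n) - mean(X).

    Near-flat spectra get "flat": every |X(n) - mean| <= eps_rel * max(X), or
    max(X) <= eps_abs (magnitudes at rounding-noise level, e.g. the residual
    DFT of a constant kernel). Total: every 3-point spectrum receives exactly
    one label.
    """
    X = np.asarray(spectrum, dtype=float)
    if X.shape != (3,):
        raise ValueError("spectrum must have exactly 3 points")
    if float(X.max()) <= eps_abs:
        return "flat"
    dev = X - X.mean()
    eps = eps_rel * float(X.max())
    if np.all(np.abs(dev) <= eps):
        return "flat"
    pattern = tuple(bool(d > 0) for d in dev)
    # deviations sum to zero, so all-above/all-below cannot occur; mixed
    # near-zero components fall through as "not above".
    return _PATTERN_TO_SHAPE[pattern]


def analyze_model(model: Conv1DNet, class_names: tuple) -> list[KernelReport]:
    """Full kernel report for one trained model's final convolutional layer."""
    assignments = map_kernels_to_class(model, class_names)
    W_last = model.conv_W[-1]  # (8, 16, 7)
    reports = []
    for a in assignments:
        k = a["kernel_index"]
        spec = kernel_spectrum(W_last[k])
        reports.append(
            KernelReport(
                kernel_index=k,
                class_weights=a["class_weights"],
                assigned_class=a["assigned_class"],
                spectrum=spec,
                shape=classify_shape(spec),
            )
        )
    return reports


def shape_counts(
    reports: list[KernelReport], region_id, class_names: tuple
) -> pd.DataFrame:
    """Count kernel shapes per (region, assigned category)."""
    rows = []
    for cat in class_names:
        counts = {s: 0 for s in SHAPE_LABELS}
        for r in reports:
            if r.assigned_class == cat:
                counts[r.shape] += 1
        rows.append({"region_id": region_id, "category": cat, **counts})
    return pd.DataFrame(rows)


def frequency_ratios(counts: pd.DataFrame) -> pd.DataFrame:
    """High/low-frequency kernel ratios n_G/n_G' and n_L'/n_L per row.

    Zero denominators yield NaN with an explicit ``*_defined`` flag rather
    than an infinity.
    """
    out = counts.copy()
    for num, den, name in (("G", "G'", "gamma_ratio"), ("L'", "L", "l_ratio")):
        defined = out[den] > 0
        out[name] = np.where(defined, out[num] / out[den].replace(0, 1), np.nan)
        out[f"{name}_defined"] = defined
    return out


def aggregate_shape_counts(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum shape counts over cross-validation folds of one region."""
    cat = pd.concat(frames, ignore_index=True)
    return (
        cat.groupby(["region_id", "category"], as_index=False)[list(SHAPE_LABELS)].sum()
    )
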