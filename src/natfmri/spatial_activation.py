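"""First-level GLM activation mapping and feature-vector extraction.

One run yields one 3D activation pattern: the t-statistic map of the task
contrast from a per-voxel ordinary-least-squares fit of the BOLD series on an
HRF-convolved task regressor plus polynomial drift terms. Activation maps are
then masked and flattened into the 1D feature vectors consumed by the
predictive model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hrf import hrf_convolved_regressor
from .synthetic_data import Volume4D

logger = logging.getLogger(__name__)

#: |t| assigned to voxels with (numerically) zero residual variance.
T_CAP = 1e6


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (time, regressors)
    names: list[str]
    contrast: np.ndarray  # (regressors,)

    def __post_init__(self):
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2D (time x regressors)")
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("one name per regressor required")
        if len(self.contrast) != self.matrix.shape[1]:
            raise ValueError("contrast length must equal regressor count")


@dataclass
class ActivationMap:
    """Per-run activation pattern: contrast t-map and contrast-effect (COPE) map."""

    stat: np.ndarray  # 3D t-statistic volume
    effect: np.ndarray  # 3D contrast-effect volume (c' beta)
    subject_id: int
    excerpt_id: int
    category: str


@dataclass
class FeatureVector:
    values: np.ndarray  # (n_mask_voxels,)
    index_map: np.ndarray  # (n_mask_voxels, 3) voxel coordinates, row-major order


def _legendre_drift(n_volumes: int, order: int) -> np.ndarray:
    """Legendre polynomial drift columns of orders 1..order on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_volumes)
    return np.column_stack(
        [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(1, order + 1)]
    ) if order >= 1 else np.empty((n_volumes, 0))


def build_design(
    onsets_s,
    durations_s,
    n_volumes: int,
    tr_seconds: float,
    hrf_params: dict | None = None,
    drift_order: int = 1,
) -> DesignMatrix:
    """Task boxcar convolved with the HRF, plus drift and intercept columns.

    The contrast vector selects the task regressor. Raises on rank deficiency,
    naming the offending columns (e.g. a zero-duration stimulus produces an
    all-zero task column).
    """
    task = hrf_convolved_regressor(
        onsets_s, durations_s, n_volumes, tr_seconds, hrf_params
    )
    drift = _legendre_drift(n_volumes, drift_order)
    intercept = np.ones((n_volumes, 1))
    X = np.column_stack([task[:, None], drift, intercept])
    names = ["task"] + [f"drift{k}" for k in range(1, drift_order + 1)] + ["intercept"]
    if n_volumes < X.shape[1]:
        raise ValueError("more regressors than time points")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = [
            name
            for j, name in enumerate(names)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")

    contrast = np.zeros(X.shape[1])
    contrast[0] = 1.0
    return DesignMatrix(matrix=X, names=names, contrast=contrast)


def fit_glm(run: Volume4D, design: DesignMatrix) -> ActivationMap:
    """Per-voxel OLS fit; returns the t-map of the design's contrast.

    t = (c'beta) / sqrt(sigma2 * c'(X'X)^-1 c) with sigma2 = RSS / (T - p).
    Voxels with zero residual variance (noiseless fits) are capped at +-T_CAP.
    """
    X = design.matrix
    T, p = X.shape
    if run.data.shape[0] != T:
        raise ValueError(
            f"run has {run.data.shape[0]} volumes but design has {T} rows"
        )
    if T <= p:
        raise ValueError("fewer time points than regressors plus one")

    Y = run.data.reshape(T, -1)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # (p, n_voxels)
    resid = Y - X @ beta
    dof = T - p
    sigma2 = np.einsum("tv,tv->v", resid, resid) / dof
    c = design.contrast
    cb = c @ beta
    var_cb = sigma2 * float(c @ xtx_inv @ c)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = cb / np.sqrt(var_cb)
    degenerate = var_cb <= np.finfo(float).tiny * 1e3
    if np.any(degenerate):
        # all-zero voxels (outside the head) are expected; warn only when a
        # voxel with real signal has a perfect fit
        n_signal = int(np.sum(degenerate & (cb != 0)))
        if n_signal:
            logger.warning(
                "%d noiseless voxels with zero residual variance; t capped at +-%g",
                n_signal,
                T_CAP,
            )
        t[degenerate] = np.sign(cb[degenerate]) * T_CAP
    t = np.clip(np.nan_to_num(t, nan=0.0, posinf=T_CAP, neginf=-T_CAP), -T_CAP, T_CAP)
    return ActivationMap(
        stat=t.reshape(run.data.shape[1:]),
        effect=cb.reshape(run.data.shape[1:]),
        subject_id=run.subject_id,
        excerpt_id=run.excerpt_id,
        category=run.category,
    )


def mask_and_flatten(
    act: ActivationMap, mask: np.ndarray, field: str = "stat"
) -> FeatureVector:
    """Flatten the in-mask voxels of an activation map in row-major order.

    ``field`` selects the map: "stat" (t) or "effect" (contrast effect).
    """
    volume = getattr(act, field)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape must match activation map shape")
    if not mask.any():
        raise ValueError("empty mask")
    coords = np.argwhere(mask)  # row-major, identical for every run
    values = volume[mask]
    return FeatureVector(values=values, index_map=coords)


def back_project(values: np.ndarray, index_map: np.ndarray, shape) -> np.ndarray:
    """Inverse of :func:`mask_and_flatten`: place values back into a 3D volume."""
    out = np.zeros(shape, dtype=float)
    out[index_map[:, 0], index_map[:, 1], index_map[:, 2]] = values
    return out


def feature_matrix(
    runs: list[Volume4D],
    design: DesignMatrix,
    mask: np.ndarray,
    field: str = "effect",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """GLM + masking for a list of runs; one activation pattern per run.

    The contrast-effect (COPE) map is the default feature field; pass
    ``field="stat"`` for t-maps. Returns (features (n_runs, n_voxels),
    labels, subject_ids, index_map).
    """
    vectors, labels, subjects = [], [], []
    index_map = None
    for run in runs:
        fv = mask_and_flatten(fit_glm(run, design), mask, field=field)
        vectors.append(fv.values)
        labels.append(run.category)
        subjects.append(run.subject_id)
        index_map = fv.index_map
    return (
        np.asarray(vectors),
        np.asarray(labels),
        np.asarray(subjects),
        index_map,
    )
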