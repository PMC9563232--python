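"""Canonical double-gamma hemodynamic response function and block regressors."""

from __future__ import annotations

import numpy as np
from scipy import stats

# Double-gamma HRF: response gamma peaking at 6 s, undershoot gamma peaking
# at 16 s, undershoot-to-peak ratio 1/6 (FEAT-like canonical shape).
DEFAULT_HRF_PARAMS = {
    "peak_delay_s": 6.0,
    "undershoot_delay_s": 16.0,
    "undershoot_ratio": 1.0 / 6.0,
    "dispersion_s": 1.0,
}


def double_gamma_hrf(t: np.ndarray, params: dict | None = None) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF at times ``t`` (seconds).

    A gamma pdf with shape ``a`` and unit scale peaks at ``a - 1``, so the
    shapes are ``delay + 1``. The curve is normalized to unit peak.
    """
    p = dict(DEFAULT_HRF_PARAMS)
    if params:
        p.update(params)
    t = np.asarray(t, dtype=float)
    disp = p["dispersion_s"]
    peak = stats.gamma.pdf(t, a=p["peak_delay_s"] / disp + 1, scale=disp)
    under = stats.gamma.pdf(t, a=p["undershoot_delay_s"] / disp + 1, scale=disp)
    h = peak - p["undershoot_ratio"] * under
    m = np.max(np.abs(h))
    if m > 0:
        h = h / m
    return h


def hrf_convolved_regressor(
    onsets_s,
    durations_s,
    n_volumes: int,
    tr_seconds: float,
    hrf_params: dict | None = None,
    oversampling: int = 10,
) -> np.ndarray:
    """Boxcar stimulus convolved with the HRF, sampled at volume acquisition times.

    The boxcar is built on a grid of ``tr/oversampling`` seconds, convolved with
    the HRF sampled on the same grid, then decimated to volume times (one sample
    at the start of each TR).
    """
    onsets = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    durations = np.atleast_1d(np.asarray(durations_s, dtype=float))
    if durations.size == 1:
        durations = np.full(onsets.shape, durations[0])
    if onsets.shape != durations.shape:
        raise ValueError("onsets_s and durations_s must have matching lengths")
    run_length_s = n_volumes * tr_seconds
    if np.any(onsets < 0) or np.any(onsets >= run_length_s):
        raise ValueError("stimulus onsets must fall inside the run")

    dt = tr_seconds / oversampling
    n_hi = n_volumes * oversampling
    box = np.zeros(n_hi)
    grid = np.arange(n_hi) * dt
    for on, dur in zip(onsets, durations):
        box[(grid >= on) & (grid < on + dur)] = 1.0

    # 32 s of HRF support is enough for the canonical shape.
    t_hrf = np.arange(0.0, 32.0, dt)
    h = double_gamma_hrf(t_hrf, hrf_params)
    conv = np.convolve(box, h)[:n_hi] * dt
    return conv[::oversampling].copy()
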