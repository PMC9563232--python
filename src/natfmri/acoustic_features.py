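"""Low-level acoustic features: Mel scale, MFCC, and spectral centroid.

MFCCs follow the classical five-step derivation: short-time Fourier transform,
projection of the power spectrum onto a Mel-spaced triangular filterbank,
logarithm, discrete cosine transform, and truncation to the leading
coefficient amplitudes. The spectral centroid is the magnitude-weighted mean
frequency of each frame, a standard brightness correlate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct
from scipy.io import wavfile

MEL_LOG_CONST = 2595.0
MEL_BREAK_HZ = 700.0


@dataclass
class AudioClip:
    samples: np.ndarray
    sample_rate: int
    category: str | None = None

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")


def load_wav(path) -> AudioClip:
    """Read a (mono or first-channel) WAV file, scaling integer PCM to [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return AudioClip(samples=np.asarray(data, dtype=float), sample_rate=int(rate))


def mel_scale(f):
    """Mel(f) = 2595 * log10(1 + f / 700); strictly increasing, Mel(0) = 0."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    out = MEL_LOG_CONST * np.log10(1.0 + f / MEL_BREAK_HZ)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m):
    m = np.asarray(m, dtype=float)
    out = MEL_BREAK_HZ * (10.0 ** (m / MEL_LOG_CONST) - 1.0)
    return float(out) if out.ndim == 0 else out


def mel_filterbank(
    sample_rate: int, n_fft: int, n_mels: int, fmin: float = 0.0, fmax: float | None = None
) -> np.ndarray:
    """Triangular filters with edges equally spaced on the Mel scale.

    Returns (n_mels, n_fft // 2 + 1); rows are nonnegative with positive sums.
    """
    fmax = sample_rate / 2 if fmax is None else fmax
    edges_mel = np.linspace(mel_scale(fmin), mel_scale(fmax), n_mels + 2)
    edges_hz = mel_to_hz(edges_mel)
    bin_hz = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_mels, len(bin_hz)))
    for i in range(n_mels):
        lo, mid, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        up = (bin_hz - lo) / max(mid - lo, 1e-12)
        down = (hi - bin_hz) / max(hi - mid, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _frames(
    samples: np.ndarray, frame_length: int, hop: int, window: str = "hann"
) -> np.ndarray:
    """Windowed frames (n_frames, frame_length); window is "hann" or "rect"."""
    x = np.asarray(samples, dtype=float)
    if len(x) < frame_length:
        raise ValueError("clip shorter than one frame")
    n_frames = 1 + (len(x) - frame_length) // hop
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    if window == "hann":
        w = np.hanning(frame_length)
    elif window == "rect":
        w = np.ones(frame_length)
    else:
        raise ValueError(f"unknown window {window!r}")
    return x[idx] * w[None, :]


def mfcc(
    clip: AudioClip,
    n_mels: int = 40,
    n_coefficients: int = 13,
    frame_length: int = 2048,
    hop: int = 512,
    log_floor: float = 1e-10,
) -> np.ndarray:
    """Mel-frequency cepstral coefficients, (n_coefficients, n_frames).

    Per frame: power spectrum -> Mel filterbank -> log (floored at
    ``log_floor``) -> orthonormal DCT-II -> first ``n_coefficients``
    amplitudes. Deterministic.
    """
    if len(clip.samples) == 0:
        raise ValueError("empty clip")
    if n_coefficients > n_mels:
        raise ValueError("n_coefficients must be <= n_mels")
    frames = _frames(clip.samples, frame_length, hop)
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    fb = mel_filterbank(clip.sample_rate, frame_length, n_mels)
    mel_power = power @ fb.T
    log_mel = np.log(np.maximum(mel_power, log_floor))
    cepstra = dct(log_mel, type=2, norm="ortho", axis=1)
    return cepstra[:, :n_coefficients].T


def spectral_centroid(
    clip: AudioClip,
    frame_length: int = 2048,
    hop: int = 512,
    power: bool = False,
    window: str = "hann",
) -> np.ndarray:
    """Per-frame spectral centroid in Hz: sum f(n) X(n) / sum X(n).

    ``X(n)`` is the magnitude at bin n (power-spectrum weighting via
    ``power=True``); f(n) is the bin center frequency. All-zero frames yield
    NaN (undefined), never 0.
    """
    frames = _frames(clip.samples, frame_length, hop, window)
    mag = np.abs(np.fft.rfft(frames, axis=1))
    if power:
        mag = mag**2
    freqs = np.fft.rfftfreq(frame_length, d=1.0 / clip.sample_rate)
    total = mag.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cent = (mag @ freqs) / total
    cent[total == 0] = np.nan
    return cent


def clip_summary(clip: AudioClip, **kwargs) -> dict:
    """Mean/sd centroid and mean MFCC vector for one clip."""
    cent = spectral_centroid(clip)
    coeffs = mfcc(clip)
    return {
        "category": clip.category,
        "centroid_mean_hz": float(np.nanmean(cent)),
        "centroid_sd_hz": float(np.nanstd(cent)),
        "mfcc_mean": coeffs.mean(axis=1).tolist(),
    }
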