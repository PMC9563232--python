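"""Synthetic naturalistic-audio fMRI data with planted spatial and temporal structure.

The generator emulates a block-design auditory study: each run is one audio
excerpt heard by one subject, recorded as ``n_volumes`` BOLD volumes at a fixed
TR. A chosen subset of atlas regions responds to the stimulus with a
category-dependent amplitude (spatial ground truth), and within those regions a
chosen fraction of voxels additionally carries a category-specific sinusoidal
frequency signature (temporal ground truth). Noise is voxel-wise AR(1) Gaussian.
Synthetic audio clips with a controllable spectral-centroid ordering accompany
the categories.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.io import wavfile

from .hrf import hrf_convolved_regressor

DEFAULT_CATEGORIES = ("CLA", "SPE")
#: Default planted signature frequencies (Hz). Both lie below the Nyquist
#: frequency 1/(2 * 1.5 s) = 0.333 Hz; CLA is the low-frequency class.
DEFAULT_CLASS_FREQ_HZ = {"CLA": 0.06, "SPE": 0.25}

BASELINE = 100.0
#: Amplitude of the stimulus response in a planted region for the
#: non-preferred category, as a fraction of ``effect_amplitude``.
NONPREFERRED_SCALE = 0.25
#: Signature-sinusoid amplitude as a multiple of ``effect_amplitude``: the
#: oscillation's DFT peak is split across bins while the block response is
#: not, so the signature needs this headroom to dominate a planted voxel's
#: periodogram.
TEMPORAL_SCALE = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror a 7-subject, 7-excerpts-per-category, two-category design
    with 60 volumes per run at TR = 1.5 s (98 runs in total).
    """

    n_subjects: int = 7
    n_excerpts_per_category: int = 7
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    n_volumes: int = 60
    tr_seconds: float = 1.5
    volume_shape: tuple[int, int, int] = (12, 12, 12)
    n_regions: int = 12
    planted_region_ids: tuple[int, ...] = (1, 2, 3, 4)
    planted_voxel_fraction: float = 0.5
    effect_amplitude: float = 1.0
    class_freq_hz: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FREQ_HZ)
    )
    ar_coefficient: float = 0.3
    noise_sd: float = 0.5
    block_on_s: float = 15.0
    block_off_s: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.n_volumes < 8:
            raise ValueError("n_volumes must be >= 8")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("duplicate category names")
        if not 0.0 < self.planted_voxel_fraction <= 1.0:
            raise ValueError("planted_voxel_fraction must be in (0, 1]")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        for cat in self.categories:
            if cat not in self.class_freq_hz:
                raise ValueError(f"no signature frequency for category {cat!r}")
            f = self.class_freq_hz[cat]
            if not 0.0 < f < nyquist:
                raise ValueError(
                    f"class_freq_hz[{cat!r}] = {f} must lie in (0, Nyquist = "
                    f"1/(2*TR) = {nyquist:.4g} Hz)"
                )

    @property
    def n_runs(self) -> int:
        return self.n_subjects * self.n_excerpts_per_category * len(self.categories)


@dataclass
class Atlas:
    """Integer parcellation (0 = background) with region names."""

    labels: np.ndarray
    names: dict[int, str]

    @property
    def region_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


@dataclass
class GroundTruth:
    """Planted structure for recovery scoring."""

    spatial_regions: frozenset[int]
    temporal_voxels: frozenset[tuple[int, int, int]]
    class_signatures: dict[str, float]
    #: category each planted region responds to most strongly
    region_preference: dict[int, str]


@dataclass
class Volume4D:
    """One fMRI run: (time, x, y, z) array plus acquisition/run metadata."""

    data: np.ndarray
    tr_seconds: float
    subject_id: int
    excerpt_id: int
    category: str

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("Volume4D.data must be 4D (t, x, y, z)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume4D.data must be finite")


def generate_toy_atlas(
    volume_shape: Sequence[int], n_regions: int, seed: int = 0
) -> tuple[Atlas, np.ndarray]:
    """Partition a box-shaped brain mask into ``n_regions`` contiguous parcels.

    The mask excludes a one-voxel border shell (when the volume is large enough)
    so that in-mask and out-of-mask voxels both exist. Mask voxels are split
    into consecutive raster-order chunks of near-equal size; region ids 1..n are
    assigned to chunks in an order shuffled by ``seed``.
    """
    volume_shape = tuple(int(s) for s in volume_shape)
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    mask = np.zeros(volume_shape, dtype=bool)
    if all(s >= 4 for s in volume_shape):
        mask[1:-1, 1:-1, 1:-1] = True
    else:
        mask[...] = True
    n_mask = int(mask.sum())
    if n_regions > n_mask:
        raise ValueError(
            f"n_regions = {n_regions} exceeds the {n_mask} voxels available in the mask"
        )

    coords = np.argwhere(mask)  # raster (C) order
    chunks = np.array_split(np.arange(n_mask), n_regions)
    rng = np.random.default_rng(seed)
    region_ids = rng.permutation(np.arange(1, n_regions + 1))
    labels = np.zeros(volume_shape, dtype=np.int32)
    for rid, chunk in zip(region_ids, chunks):
        c = coords[chunk]
        labels[c[:, 0], c[:, 1], c[:, 2]] = rid
    names = {int(i): f"region_{int(i):03d}" for i in range(1, n_regions + 1)}
    return Atlas(labels=labels, names=names), mask


def make_ground_truth(config: SimConfig, atlas: Atlas, mask: np.ndarray) -> GroundTruth:
    """Plant spatially discriminative regions and temporally discriminative voxels.

    Planted regions alternate their preferred category (round-robin over the
    sorted region ids), so both classes contribute positive and negative
    classifier evidence. Within each planted region a fraction
    ``planted_voxel_fraction`` of in-mask voxels carries the sinusoidal class
    signature.
    """
    atlas_ids = set(atlas.region_ids)
    planted = sorted(set(int(i) for i in config.planted_region_ids))
    missing = set(planted) - atlas_ids
    if missing:
        raise ValueError(f"planted regions absent from atlas: {sorted(missing)}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    preference: dict[int, str] = {}
    temporal: set[tuple[int, int, int]] = set()
    for j, rid in enumerate(planted):
        preference[rid] = config.categories[j % len(config.categories)]
        coords = np.argwhere((atlas.labels == rid) & mask)
        n_pick = max(1, int(round(config.planted_voxel_fraction * len(coords))))
        pick = rng.choice(len(coords), size=min(n_pick, len(coords)), replace=False)
        temporal.update(tuple(int(v) for v in coords[i]) for i in pick)
    return GroundTruth(
        spatial_regions=frozenset(planted),
        temporal_voxels=frozenset(temporal),
        class_signatures=dict(config.class_freq_hz),
        region_preference=preference,
    )


def _run_rng(config: SimConfig, subject_id: int, excerpt_id: int, category: str):
    cat_idx = list(config.categories).index(category)
    ss = np.random.SeedSequence([config.seed, subject_id, excerpt_id, cat_idx])
    return np.random.default_rng(ss)


def block_design_timing(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """On/off block onsets and durations covering the run."""
    run_s = config.n_volumes * config.tr_seconds
    period = config.block_on_s + config.block_off_s
    onsets = np.arange(0.0, run_s, period)
    durations = np.full(onsets.shape, config.block_on_s)
    return onsets, durations


def generate_run(
    config: SimConfig,
    atlas: Atlas,
    mask: np.ndarray,
    truth: GroundTruth,
    subject_id: int,
    excerpt_id: int,
    category: str,
) -> Volume4D:
    """Simulate one run as baseline + planted signal + AR(1) noise.

    Inside planted regions the HRF-convolved block response has amplitude
    ``effect_amplitude`` for the region's preferred category and a quarter of
    that otherwise, with AR(1) noise scaled proportionally to the response
    amplitude (multiplicative physiological noise); planted temporal voxels
    additionally carry a sinusoid at the category's signature frequency.
    Voxels outside the mask are zero.
    """
    if category not in config.categories:
        raise ValueError(f"unknown category {category!r}")
    T = config.n_volumes
    shape = tuple(config.volume_shape)
    n_vox = int(np.prod(shape))

    onsets, durations = block_design_timing(config)
    task = hrf_convolved_regressor(onsets, durations, T, config.tr_seconds)
    peak = np.max(np.abs(task))
    if peak > 0:
        task = task / peak  # unit peak: effect_amplitude is the response amplitude
    t_s = np.arange(T) * config.tr_seconds
    sin_sig = TEMPORAL_SCALE * config.effect_amplitude * np.sin(
        2.0 * np.pi * truth.class_signatures[category] * t_s
    )

    amp = np.zeros(shape)
    for rid in truth.spatial_regions:
        scale = 1.0 if truth.region_preference[rid] == category else NONPREFERRED_SCALE
        amp[atlas.labels == rid] = config.effect_amplitude * scale

    data = np.zeros((T, n_vox))
    amp_flat = amp.reshape(-1)
    data += task[:, None] * amp_flat[None, :]

    tv = np.zeros(shape, dtype=bool)
    for c in truth.temporal_voxels:
        tv[c] = True
    data[:, tv.reshape(-1)] += sin_sig[:, None]

    if config.noise_sd > 0:
        rng = _run_rng(config, subject_id, excerpt_id, category)
        rho = config.ar_coefficient
        innov_sd = config.noise_sd * np.sqrt(1.0 - rho**2)
        noise = np.empty((T, n_vox))
        # start each voxel's AR(1) chain at its stationary distribution
        noise[0] = rng.normal(0.0, config.noise_sd, size=n_vox)
        eps = rng.normal(0.0, innov_sd, size=(T - 1, n_vox))
        for t in range(1, T):
            noise[t] = rho * noise[t - 1] + eps[t - 1]
        # Multiplicative (signal-proportional) noise in responsive voxels:
        # physiological BOLD noise scales with response amplitude, and this
        # keeps the variance-normalized series of a spatial-only voxel
        # class-independent, so only the planted frequency signatures carry
        # temporal class information.
        if config.effect_amplitude > 0:
            noise_scale = np.where(
                amp_flat > 0, amp_flat / config.effect_amplitude, 1.0
            )
            noise *= noise_scale[None, :]
        data += noise

    data += BASELINE
    data *= mask.reshape(-1)[None, :]
    return Volume4D(
        data=data.reshape((T,) + shape),
        tr_seconds=config.tr_seconds,
        subject_id=subject_id,
        excerpt_id=excerpt_id,
        category=category,
    )


def generate_dataset(
    config: SimConfig,
) -> tuple[Atlas, np.ndarray, GroundTruth, list[Volume4D]]:
    """Generate the full balanced dataset: one run per (subject, excerpt, category)."""
    atlas, mask = generate_toy_atlas(config.volume_shape, config.n_regions, config.seed)
    truth = make_ground_truth(config, atlas, mask)
    runs = [
        generate_run(config, atlas, mask, truth, subject, excerpt, category)
        for subject in range(config.n_subjects)
        for category in config.categories
        for excerpt in range(config.n_excerpts_per_category)
    ]
    return atlas, mask, truth, runs


# ---------------------------------------------------------------------------
# Synthetic audio
# ---------------------------------------------------------------------------

#: Tone recipes per audio category: (frequencies Hz, relative amplitudes).
#: The "dark" class concentrates energy low (spectral centroid ~400 Hz); the
#: "bright" class sits higher (~1000 Hz) and is amplitude-modulated, giving the
#: documented ordering centroid(bright) > centroid(dark).
AUDIO_RECIPES = {
    "CLA": ([250.0, 350.0, 450.0, 550.0], [1.0, 1.0, 1.0, 1.0], 0.0),
    "SPE": ([700.0, 900.0, 1100.0, 1300.0], [1.0, 1.0, 1.0, 1.0], 6.0),
}
AUDIO_ALIASES = {"dark": "CLA", "bright": "SPE"}


def synthesize_tone(freq_hz: float, duration_s: float, sample_rate: int) -> np.ndarray:
    """Pure sine tone (single spectral peak at ``freq_hz``)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    return np.sin(2.0 * np.pi * freq_hz * t)


def synthesize_audio(
    category: str, duration_s: float, sample_rate: int = 22050, seed: int = 0
) -> np.ndarray:
    """Category-specific tone mixture with seed-deterministic phases.

    The bright category carries a slow tremolo (amplitude modulation), making
    its spectrum both higher and more volatile than the dark category's.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    key = AUDIO_ALIASES.get(category, category)
    if key not in AUDIO_RECIPES:
        raise ValueError(f"unknown audio category {category!r}")
    freqs, amps, tremolo_hz = AUDIO_RECIPES[key]
    key_code = zlib.crc32(key.encode()) % 2**31
    rng = np.random.default_rng(np.random.SeedSequence([seed, key_code]))
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.zeros(n)
    for f, a in zip(freqs, amps):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += a * np.sin(2.0 * np.pi * f * t + phase)
    if tremolo_hz > 0:
        x *= 1.0 + 0.5 * np.sin(2.0 * np.pi * tremolo_hz * t)
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_nifti(path, array3d_or_4d: np.ndarray, voxel_size_mm: float = 4.0) -> None:
    """Write a (t, x, y, z) or (x, y, z) array as NIfTI-1 (time as last axis)."""
    import nibabel as nib

    arr = np.asarray(array3d_or_4d)
    if arr.ndim == 4:
        arr = np.moveaxis(arr, 0, -1)
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(path))


def save_atlas_nifti(path, atlas: Atlas, voxel_size_mm: float = 4.0) -> None:
    import nibabel as nib

    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), str(path))


def save_wav(path, samples: np.ndarray, sample_rate: int) -> None:
    """Write mono PCM-16 WAV."""
    x = np.asarray(samples, dtype=float)
    peak = np.max(np.abs(x)) or 1.0
    pcm = np.round(x / peak * 32767).astype(np.int16)
    wavfile.write(str(path), sample_rate, pcm)


def save_ground_truth(path, truth: GroundTruth) -> None:
    payload = {
        "spatial_regions": sorted(truth.spatial_regions),
        "temporal_voxels": sorted(list(v) for v in truth.temporal_voxels),
        "class_signatures": truth.class_signatures,
        "region_preference": {str(k): v for k, v in truth.region_preference.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
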