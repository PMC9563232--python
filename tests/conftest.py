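import numpy as np
import pytest

from natfmri.synthetic_data import (
    SimConfig,
    generate_dataset,
    generate_toy_atlas,
    make_ground_truth,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated study shared by the spatial-path tests:
    4 subjects x 4 excerpts x 2 categories on a 10^3 toy brain."""
    cfg = SimConfig(
        n_subjects=4,
        n_excerpts_per_category=4,
        volume_shape=(10, 10, 10),
        n_regions=16,
        planted_region_ids=(1, 2, 3, 4),
        seed=101,
    )
    atlas, mask, truth, runs = generate_dataset(cfg)
    return cfg, atlas, mask, truth, runs


@pytest.fixture(scope="session")
def toy_atlas():
    cfg = SimConfig(
        n_subjects=2,
        n_excerpts_per_category=2,
        volume_shape=(8, 8, 8),
        n_regions=6,
        planted_region_ids=(1, 2),
        seed=5,
    )
    atlas, mask = generate_toy_atlas(cfg.volume_shape, cfg.n_regions, cfg.seed)
    truth = make_ground_truth(cfg, atlas, mask)
    return cfg, atlas, mask, truth


@pytest.fixture(scope="session")
def demo_run_dir(tmp_path_factory):
    """One full demo pipeline execution shared by the end-to-end tests."""
    from natfmri.pipeline import run_pipeline

    outdir = tmp_path_factory.mktemp("demo_run")
    report = run_pipeline({}, outdir)
    return outdir, report


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
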