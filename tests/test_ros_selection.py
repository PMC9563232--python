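"""Region scoring (feature-voxel ratio) and ROS assembly."""

import numpy as np
import pytest

from natfmri.predictive_model import SignificanceMap
from natfmri.ros_selection import (
    RegionScore,
    region_feature_ratio,
    select_ros,
)
from natfmri.synthetic_data import Atlas


def _sig(selected_idx, signs, n_features, method="bootstrap"):
    selected = np.zeros(n_features, dtype=bool)
    selected[selected_idx] = True
    sign = np.zeros(n_features, dtype=np.int8)
    sign[selected_idx] = signs
    return SignificanceMap(
        statistic=np.zeros(n_features),
        selected=selected,
        sign=sign,
        method=method,
        classes=("A", "B"),
    )


@pytest.fixture
def flat_atlas():
    """A 1 x 1 x 200 volume: region 1 = first 100 voxels, region 2 = rest."""
    labels = np.zeros((1, 1, 200), dtype=np.int32)
    labels[0, 0, :100] = 1
    labels[0, 0, 100:] = 2
    atlas = Atlas(labels=labels, names={1: "front", 2: "back"})
    index_map = np.argwhere(np.ones_like(labels, dtype=bool))
    return atlas, index_map


class TestRegionFeatureRatio:
    def test_ratio_arithmetic(self, flat_atlas):
        atlas, index_map = flat_atlas
        sig = _sig(np.arange(25), [1] * 25, 200)
        scores = region_feature_ratio(sig, atlas, index_map)
        by_key = {(s.region_id, s.sign): s for s in scores}
        s1 = by_key[(1, "positive")]
        assert (s1.n, s1.m, s1.r) == (25, 100, 0.25)
        assert by_key[(2, "positive")].r == 0.0
        assert by_key[(1, "negative")].r == 0.0

    def test_counts_partition_selected_voxels(self, flat_atlas):
        atlas, index_map = flat_atlas
        rng = np.random.default_rng(0)
        idx = rng.choice(200, size=60, replace=False)
        signs = rng.choice([-1, 1], size=60)
        sig = _sig(idx, signs, 200)
        scores = region_feature_ratio(sig, atlas, index_map)
        assert sum(s.n for s in scores) == 60

    def test_ratio_invariant_to_nonselected_relabeling(self, flat_atlas):
        atlas, index_map = flat_atlas
        sig = _sig(np.arange(10), [1] * 10, 200)
        base = {(s.region_id, s.sign): s.r
                for s in region_feature_ratio(sig, atlas, index_map)}
        # flip statistic values of non-selected voxels: ratios unchanged
        sig2 = _sig(np.arange(10), [1] * 10, 200)
        sig2.statistic[50:] = 99.0
        after = {(s.region_id, s.sign): s.r
                 for s in region_feature_ratio(sig2, atlas, index_map)}
        assert base == after

    def test_region_score_validates_bounds(self):
        with pytest.raises(ValueError):
            RegionScore(region_id=1, name="x", sign="positive",
                        method="bootstrap", n=1, m=0, r=0.5)


def _score(rid, r, sign="positive", method="bootstrap", n=None):
    return RegionScore(
        region_id=rid, name=f"region_{rid:03d}", sign=sign, method=method,
        n=n if n is not None else max(1, int(round(r * 100))), m=100, r=r,
    )


class TestSelectROS:
    def test_union_of_four_lists(self):
        """Four top-6 lists (24 entries) with 3 shared positive and 5 shared
        negative regions combine into 16 distinct regions, with the shared
        ones in the per-sign intersections."""
        lists = {
            ("positive", "bootstrap"): [1, 2, 3, 4, 5, 6],
            ("positive", "RFE"): [1, 2, 3, 7, 8, 9],
            ("negative", "bootstrap"): [10, 11, 12, 13, 14, 15],
            ("negative", "RFE"): [10, 11, 12, 13, 14, 16],
        }
        scores_by_method = {"bootstrap": [], "RFE": []}
        for (sign, method), ids in lists.items():
            for rank, rid in enumerate(ids):
                scores_by_method[method].append(
                    _score(rid, r=0.9 - 0.1 * rank, sign=sign, method=method)
                )
        ros = select_ros(scores_by_method, k=6)
        assert len(ros.region_ids) == 16
        assert ros.intersection["positive"] == [1, 2, 3]
        assert ros.intersection["negative"] == [10, 11, 12, 13, 14]

    def test_identical_lists_full_intersection(self):
        scores_by_method = {
            m: [_score(rid, r=0.9 - 0.1 * i, method=m) for i, rid in enumerate(range(1, 7))]
            for m in ("bootstrap", "RFE")
        }
        ros = select_ros(scores_by_method, k=6)
        assert ros.region_ids == [1, 2, 3, 4, 5, 6]
        assert ros.intersection["positive"] == [1, 2, 3, 4, 5, 6]

    def test_tie_at_rank_k_prefers_lower_region_id(self):
        scores = {"bootstrap": [
            _score(9, 0.5), _score(4, 0.3), _score(2, 0.3), _score(7, 0.3),
        ]}
        ros = select_ros(scores, k=2)
        assert ros.top_lists[("positive", "bootstrap")] == [9, 2]

    def test_zero_feature_regions_never_selected(self):
        scores = {"bootstrap": [_score(1, 0.4), _score(2, 0.0, n=0), _score(3, 0.0, n=0)]}
        ros = select_ros(scores, k=3)
        assert ros.top_lists[("positive", "bootstrap")] == [1]

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError, match="k"):
            select_ros({"bootstrap": [_score(1, 0.5)]}, k=0)


class TestEndToEndRecovery:
    def test_planted_regions_top_ranked(self, small_dataset):
        """Planted regions occupy the top ratio ranks; ROS recovery Jaccard >= 0.8."""
        from natfmri.predictive_model import bootstrap_feature_test, rfe_select
        from natfmri.spatial_activation import build_design, feature_matrix
        from natfmri.synthetic_data import block_design_timing

        cfg, atlas, mask, truth, runs = small_dataset
        onsets, durations = block_design_timing(cfg)
        design = build_design(onsets, durations, cfg.n_volumes, cfg.tr_seconds)
        X, y, subj, idxmap = feature_matrix(runs, design, mask)
        planted_flat = np.isin(atlas.labels, list(truth.spatial_regions))[mask]
        sigs = {
            "bootstrap": bootstrap_feature_test(X, y, B=100, seed=11),
            "RFE": rfe_select(X, y, n_keep=int(planted_flat.sum())),
        }
        scores = {m: region_feature_ratio(s, atlas, idxmap, mask)
                  for m, s in sigs.items()}
        # matched k: planted regions split evenly between the two signs
        ros = select_ros(scores, k=len(truth.spatial_regions) // 2)
        planted = set(truth.spatial_regions)
        got = set(ros.region_ids)
        assert len(got & planted) / len(got | planted) >= 0.8
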