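"""Region-of-significance (ROS) selection from classifier feature maps.

Each atlas region is scored by its feature-voxel ratio r = n / m, where n is
the number of classifier-selected voxels falling in the region (separately for
positive- and negative-sign features) and m is the region's total voxel count.
The ROS set is the union of the top-k regions per (sign x method) list, with
the per-sign intersection across methods also reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .predictive_model import SignificanceMap
from .spatial_activation import back_project
from .synthetic_data import Atlas

logger = logging.getLogger(__name__)

SIGNS = ("positive", "negative")


@dataclass
class RegionScore:
    region_id: int
    name: str
    sign: str  # "positive" | "negative"
    method: str
    n: int  # selected feature voxels in the region
    m: int  # total region voxels
    r: float  # n / m

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("region must contain at least one voxel")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("feature-voxel ratio must lie in [0, 1]")


@dataclass
class ROSSet:
    """Selected regions with provenance.

    ``regions`` maps region id -> {"name", "signs", "methods"}; ``top_lists``
    keeps the per-(sign, method) top-k region ids; ``intersection`` the
    per-sign across-method intersections; ``outside_atlas`` counts selected
    voxels not covered by any region.
    """

    regions: dict[int, dict]
    top_lists: dict[tuple[str, str], list[int]]
    intersection: dict[str, list[int]] = field(default_factory=dict)
    outside_atlas: dict[str, int] = field(default_factory=dict)

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.regions)


def region_feature_ratio(
    sig: SignificanceMap,
    atlas: Atlas,
    index_map: np.ndarray,
    mask: np.ndarray | None = None,
) -> list[RegionScore]:
    """Score every atlas region by the feature-voxel ratio r_i = n_i / m_i, per sign.

    ``index_map`` maps the flat feature positions of ``sig`` back to voxel
    coordinates (as produced by mask_and_flatten). When ``mask`` is given,
    region sizes m count only in-mask voxels. Selected voxels outside every
    region are counted and logged, not silently dropped.
    """
    labels = atlas.labels
    if mask is not None and mask.shape != labels.shape:
        raise ValueError("mask and atlas shapes differ")
    support = np.ones_like(labels, dtype=bool) if mask is None else np.asarray(mask, bool)

    scores: list[RegionScore] = []
    sign_values = {"positive": 1, "negative": -1}
    outside = {}
    for sign_name, sval in sign_values.items():
        flags = (sig.selected) & (sig.sign == sval)
        vol = back_project(flags.astype(float), index_map, labels.shape) > 0.5
        outside[sign_name] = int(np.sum(vol & (labels == 0)))
        for rid in atlas.region_ids:
            region = (labels == rid) & support
            m = int(region.sum())
            if m == 0:
                logger.warning("region %d has no in-mask voxels; omitted", rid)
                continue
            n = int(np.sum(vol & region))
            scores.append(
                RegionScore(
                    region_id=rid,
                    name=atlas.names.get(rid, str(rid)),
                    sign=sign_name,
                    method=sig.method,
                    n=n,
                    m=m,
                    r=n / m,
                )
            )
    for sign_name, cnt in outside.items():
        if cnt:
            logger.info(
                "%d selected %s-sign voxels fall outside every atlas region",
                cnt,
                sign_name,
            )
    return scores


def scores_to_frame(scores: list[RegionScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": s.region_id,
                "name": s.name,
                "sign": s.sign,
                "method": s.method,
                "n": s.n,
                "m": s.m,
                "r": s.r,
            }
            for s in scores
        ]
    )


def _top_k(scores: list[RegionScore], k: int, rank_by: str) -> list[int]:
    # regions without any selected feature voxel cannot be "regions with the
    # most significant features"; ties at rank k break by ascending region id
    eligible = [s for s in scores if s.n > 0]
    ordered = sorted(eligible, key=lambda s: (-getattr(s, rank_by), s.region_id))
    if len(ordered) < k:
        logger.warning("only %d scored regions available for top-%d", len(ordered), k)
    return [s.region_id for s in ordered[:k]]


def select_ros(
    scores_by_method: dict[str, list[RegionScore]],
    k: int = 6,
    rank_by: str = "r",
) -> ROSSet:
    """Assemble the ROS set: top-k per (sign x method), union across lists.

    ``scores_by_method`` maps method name -> the full RegionScore list produced
    by :func:`region_feature_ratio` for that method. ``rank_by`` is "r"
    (feature-voxel ratio, default) or "n" (raw feature count).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if rank_by not in ("r", "n"):
        raise ValueError("rank_by must be 'r' or 'n'")

    top_lists: dict[tuple[str, str], list[int]] = {}
    names: dict[int, str] = {}
    for method, scores in scores_by_method.items():
        for s in scores:
            names[s.region_id] = s.name
        for sign in SIGNS:
            per = [s for s in scores if s.sign == sign]
            top_lists[(sign, method)] = _top_k(per, k, rank_by)

    regions: dict[int, dict] = {}
    for (sign, method), ids in top_lists.items():
        for rid in ids:
            entry = regions.setdefault(
                rid, {"name": names.get(rid, str(rid)), "signs": set(), "methods": set()}
            )
            entry["signs"].add(sign)
            entry["methods"].add(method)
    for entry in regions.values():
        entry["signs"] = sorted(entry["signs"])
        entry["methods"] = sorted(entry["methods"])

    methods = list(scores_by_method)
    intersection = {}
    for sign in SIGNS:
        sets = [set(top_lists[(sign, m)]) for m in methods]
        intersection[sign] = sorted(set.intersection(*sets)) if sets else []
    return ROSSet(regions=regions, top_lists=top_lists, intersection=intersection)


def default_k(n_regions: int, k: int = 6) -> int:
    """Paper-scale default of 6 per list, scaled down for toy atlases."""
    return min(k, max(1, int(np.ceil(n_regions / 3))))
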