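"""Cross-channel ROI matching and the 488/445 intensity ratio.

ROIs detected independently in the 445 nm and 488 nm images of the same field
are matched one-to-one by centroid proximity: among matchings that use only
pairs closer than ``max_dist_px``, the maximum-cardinality matching with
minimum total centroid distance is chosen (optimal assignment — greedy
matching would be order-dependent).  Unmatched ROIs are discarded, as are
pairs whose minimum pixel intensity falls below a floor.  Each surviving pair
carries the ratio of ROI-mean intensities, 488 over 445.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .segmentation import Roi

__all__ = ["RoiPair", "pair_rois", "filter_pairs", "pair_ratio"]

#: Cost placed on disallowed assignments; must dominate any sum of real
#: distances so that the assignment maximizes the number of allowed pairs.
_DISALLOWED = 1e9


@dataclass(frozen=True, eq=False)
class RoiPair:
    roi_445: Roi
    roi_488: Roi
    centroid_distance_px: float
    ratio: float


def pair_ratio(roi_445: Roi, roi_488: Roi) -> float:
    """Ratio of ROI-mean background-subtracted intensities, 488 over 445."""
    if roi_445.mean_intensity <= 0:
        raise ValueError("degenerate ROI: non-positive 445 nm mean intensity")
    return roi_488.mean_intensity / roi_445.mean_intensity


def pair_rois(
    rois_445: list[Roi],
    rois_488: list[Roi],
    max_dist_px: float = 3.0,
) -> list[RoiPair]:
    """Optimal one-to-one matching of ROIs with a hard distance gate.

    Returns pairs sorted by (roi_id_445, roi_id_488); each ROI appears in at
    most one pair.  Equals the brute-force minimum-total-distance assignment
    (oracle-tested for small instances).
    """
    if max_dist_px <= 0:
        raise ValueError("max_dist_px must be > 0")
    if not rois_445 or not rois_488:
        return []
    a = np.array([r.centroid for r in rois_445], dtype=float)
    b = np.array([r.centroid for r in rois_488], dtype=float)
    dist = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    cost = np.where(dist <= max_dist_px, dist, _DISALLOWED)
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    for i, j in zip(rows, cols):
        if dist[i, j] > max_dist_px:
            continue
        r445, r488 = rois_445[i], rois_488[j]
        pairs.append(
            RoiPair(
                roi_445=r445,
                roi_488=r488,
                centroid_distance_px=float(dist[i, j]),
                ratio=pair_ratio(r445, r488),
            )
        )
    pairs.sort(key=lambda p: (p.roi_445.roi_id, p.roi_488.roi_id))
    return pairs


def filter_pairs(pairs: list[RoiPair], min_pixel_intensity: float = 5.0) -> list[RoiPair]:
    """Drop pairs where either ROI contains pixels below the intensity floor."""
    if min_pixel_intensity < 0:
        raise ValueError("min_pixel_intensity must be >= 0")
    return [
        p
        for p in pairs
        if p.roi_445.min_intensity >= min_pixel_intensity
        and p.roi_488.min_intensity >= min_pixel_intensity
    ]
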