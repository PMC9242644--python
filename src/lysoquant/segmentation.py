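"""Punctate-organelle segmentation: background subtraction, Otsu, components.

Each excitation channel is processed independently: a local background
estimate (grayscale opening with a disk, a rolling-ball analog) is subtracted,
the Otsu method picks a global threshold, and connected components above a
minimum area become ROIs.  The Otsu implementation is deliberately explicit —
candidate thresholds are histogram bin edges, between-class variance is
computed from the exact pixel partition, ties break toward the lowest
threshold — and is pinned by a brute-force oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label
from skimage.morphology import disk, opening

__all__ = ["Roi", "subtract_background", "otsu_threshold", "extract_rois"]


@dataclass(frozen=True, eq=False)
class Roi:
    """One segmented punctum in one channel.

    ``pixels`` is an (N, 2) array of 0-based (row, col) coordinates; the
    centroid is the unweighted mean of pixel coordinates; intensities are
    background-subtracted.
    """

    roi_id: int
    channel: int | None
    pixels: np.ndarray
    centroid: tuple[float, float]
    area_px: int
    mean_intensity: float
    min_intensity: float


def subtract_background(image: np.ndarray, radius_px: int) -> np.ndarray:
    """Subtract a local background (grayscale opening with a disk), floor 0.

    The opening removes structures smaller than the disk from the background
    estimate, so isolated bright puncta survive subtraction at full amplitude
    while smooth gradients and offsets are removed.
    """
    image = np.asarray(image, dtype=float)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if radius_px > min(image.shape) / 2:
        raise ValueError("radius_px larger than half the smaller image dimension")
    background = opening(image, disk(int(radius_px)))
    return np.clip(image - background, 0.0, None)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold: the bin edge maximizing between-class variance.

    Candidates are the lower ``n_bins`` edges of a uniform histogram over
    [min, max]; for each candidate the classes are (pixels <= edge) vs
    (pixels > edge) and the criterion is w0*w1*(mu0 - mu1)^2 computed from the
    exact pixel values.  Ties break toward the lowest threshold.  Foreground
    is defined as pixels strictly greater than the returned threshold.
    """
    values = np.sort(np.asarray(image, dtype=float).ravel())
    if values.size < 2 or values[0] == values[-1]:
        raise ValueError("no threshold exists: image has fewer than 2 distinct values")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(values[0], values[-1], n_bins + 1)[:-1]
    n0 = np.searchsorted(values, edges, side="right")
    n = values.size
    csum = np.cumsum(values)
    total = csum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sum0 = np.where(n0 > 0, csum[np.clip(n0 - 1, 0, n - 1)], 0.0)
        mu0 = sum0 / n0
        mu1 = (total - sum0) / (n - n0)
        w0 = n0 / n
        bcv = w0 * (1.0 - w0) * (mu0 - mu1) ** 2
    bcv[(n0 == 0) | (n0 == n)] = -np.inf
    best = int(np.argmax(bcv))  # argmax returns the first (lowest) maximizer
    if not np.isfinite(bcv[best]):
        raise ValueError("no threshold exists: degenerate histogram")
    return float(edges[best])


def extract_rois(
    image: np.ndarray,
    threshold: float,
    min_area: int = 4,
    connectivity: int = 8,
    channel: int | None = None,
) -> list[Roi]:
    """Connected components of ``image > threshold`` with area >= min_area.

    ROIs are pairwise disjoint; ordering is deterministic, by each
    component's first pixel in row-major scan order.  Intensity statistics
    are taken from ``image`` (assumed background-subtracted).
    """
    image = np.asarray(image, dtype=float)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = image > threshold
    if not mask.any():
        return []
    lab = sk_label(mask, connectivity=1 if connectivity == 4 else 2)
    flat = lab.ravel()
    labels, first_idx = np.unique(flat, return_index=True)
    keep = labels > 0
    labels, first_idx = labels[keep], first_idx[keep]
    order = np.argsort(first_idx)  # row-major order of each component's top-left pixel
    areas = np.bincount(flat)
    slices = ndimage.find_objects(lab)
    rois: list[Roi] = []
    roi_id = 0
    for lbl in labels[order]:
        if areas[lbl] < min_area:
            continue
        sl = slices[lbl - 1]
        local = lab[sl] == lbl
        rr, cc = np.nonzero(local)
        rows = rr + sl[0].start
        cols = cc + sl[1].start
        vals = image[rows, cols]
        roi_id += 1
        rois.append(
            Roi(
                roi_id=roi_id,
                channel=channel,
                pixels=np.column_stack([rows, cols]),
                centroid=(float(rows.mean()), float(cols.mean())),
                area_px=int(rows.size),
                mean_intensity=float(vals.mean()),
                min_intensity=float(vals.min()),
            )
        )
    return rois
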