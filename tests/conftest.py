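"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pytest

from lysoquant.segmentation import Roi
from lysoquant.synth_imaging import (
    Cell,
    GroundTruthLaw,
    Lysosome,
    NoiseModel,
    SyntheticScene,
)


@pytest.fixture
def law() -> GroundTruthLaw:
    return GroundTruthLaw(r_min=0.2, r_max=2.0, ph50=4.8, slope_h=1.0)


@pytest.fixture
def noiseless() -> NoiseModel:
    return NoiseModel.noiseless()


def make_roi(
    roi_id: int,
    centroid: tuple[float, float],
    channel: int | None = None,
    area_px: int = 25,
    mean_intensity: float = 100.0,
    min_intensity: float = 50.0,
) -> Roi:
    """Lightweight ROI for pairing/quantification tests (pixels are a stub)."""
    r, c = int(round(centroid[0])), int(round(centroid[1]))
    return Roi(
        roi_id=roi_id,
        channel=channel,
        pixels=np.array([[r, c]]),
        centroid=(float(centroid[0]), float(centroid[1])),
        area_px=area_px,
        mean_intensity=mean_intensity,
        min_intensity=min_intensity,
    )


def grid_scene(
    positions: list[tuple[float, float]],
    true_phs: list[float],
    law: GroundTruthLaw,
    shape: tuple[int, int] = (200, 200),
    radius_px: float = 2.0,
    dye: float = 3000.0,
    pixel_size_um: float = 0.1,
    condition: str = "test",
) -> SyntheticScene:
    """Scene with hand-placed lysosomes inside one big elliptical cell."""
    cell = Cell(cell_id=1, center=(shape[0] / 2, shape[1] / 2),
                semi_axes=(shape[0] / 2, shape[1] / 2))
    lysosomes = tuple(
        Lysosome(cell_id=1, lysosome_id=i + 1, row=r, col=c,
                 radius_px=radius_px, dye_amount=dye, true_ph=ph)
        for i, ((r, c), ph) in enumerate(zip(positions, true_phs))
    )
    return SyntheticScene(image_shape=shape, pixel_size_um=pixel_size_um,
                          cells=(cell,), lysosomes=lysosomes, law=law,
                          condition_label=condition)


# ---------------------------------------------------------------------------
# Independent oracles

def otsu_bruteforce_mask(image: np.ndarray) -> np.ndarray:
    """Exhaustive Otsu: try every distinct value as threshold (classes
    <= t vs > t), maximize w0*w1*(mu0-mu1)^2, ties toward the lowest
    threshold.  Returns the foreground mask."""
    v = np.asarray(image, dtype=float).ravel()
    candidates = np.unique(v)[:-1]  # thresholding at max leaves no foreground
    best_t, best_score = None, -np.inf
    for t in candidates:
        lo = v[v <= t]
        hi = v[v > t]
        w0 = lo.size / v.size
        score = w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2
        if score > best_score + 1e-12:
            best_score, best_t = score, t
    return np.asarray(image, dtype=float) > best_t


@lru_cache(maxsize=None)
def _perms(k: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(k))), dtype=np.intp)


def assignment_bruteforce(
    a: np.ndarray, b: np.ndarray, max_dist: float
) -> tuple[int, float]:
    """Enumerate all one-to-one assignments on the padded square cost matrix
    (disallowed/dummy entries at a large constant), return the number of
    allowed pairs and their total distance for the optimum."""
    big = 1e9
    n, m = len(a), len(b)
    k = max(n, m)
    if k == 0:
        return 0, 0.0
    dist = np.full((k, k), big)
    if n and m:
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        dist[:n, :m] = np.where(d <= max_dist, d, big)
    perms = _perms(k)
    costs = dist[np.arange(k)[None, :], perms].sum(axis=1)
    best = perms[int(np.argmin(costs))]
    total, count = 0.0, 0
    for i, j in enumerate(best):
        if dist[i, j] < big:
            total += dist[i, j]
            count += 1
    return count, total
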