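"""Synthetic dual-excitation ratiometric imaging data with known ground truth.

This module emulates the raw material of an excitation-ratio lysosomal pH
experiment: fields of view containing cells whose lysosomes are loaded with a
ratiometric dye (Oregon-Green-like, apparent pKa ~4.8).  Each lysosome is
rendered into a pair of images — one per excitation wavelength (445 nm and
488 nm) — such that the 488/445 intensity ratio of the spot equals a known
sigmoidal function of the lysosome's true pH.  The 445 nm channel is
pH-independent by construction (the reference-channel contract), so the
ground-truth ratio of every spot is exact and every downstream stage
(segmentation, pairing, calibration, inversion) can be tested quantitatively.

Calibration series emulate the ionophore clamp used to build ratio-vs-pH
standard curves: lysosomal pH is forced to a set of buffer pH values and
4–5 single-cell image pairs are rendered per buffer.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "GroundTruthLaw",
    "NoiseModel",
    "Cell",
    "Lysosome",
    "SyntheticScene",
    "SceneConfig",
    "ImagePair",
    "DEFAULT_BUFFER_PHS",
    "make_scene",
    "render_image_pair",
    "make_calibration_series",
    "write_image_pair",
    "write_condition_images",
    "write_calibration_series",
]

#: Buffer pH values of the calibration clamp, high to low.
DEFAULT_BUFFER_PHS: tuple[float, ...] = (7.0, 6.0, 5.0, 4.5, 4.0, 3.0)

#: Range of physically meaningful lysosomal pH for the generator: the
#: calibration buffer span plus margin.
PH_BOUNDS: tuple[float, float] = (3.0, 7.5)


@dataclass(frozen=True)
class GroundTruthLaw:
    """Sigmoidal ratio–pH law R(pH) used to render the 488 nm channel.

    R(pH) = r_min + (r_max - r_min) / (1 + 10^(slope_h * (ph50 - pH)))

    Strictly increasing in pH for slope_h > 0.  ``ph50`` is the apparent pKa
    of the dye (midpoint of the sigmoid); defaults mirror an Oregon-Green-like
    probe with pKa 4.8.
    """

    r_min: float = 0.2
    r_max: float = 2.0
    ph50: float = 4.8
    slope_h: float = 1.0

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min > 0):
            raise ValueError("require r_max > r_min > 0")
        if self.slope_h <= 0:
            raise ValueError("require slope_h > 0")

    def ratio(self, ph):
        """Evaluate R(pH); accepts scalars or arrays."""
        ph = np.asarray(ph, dtype=float)
        out = self.r_min + (self.r_max - self.r_min) / (
            1.0 + 10.0 ** (self.slope_h * (self.ph50 - ph))
        )
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class NoiseModel:
    """Detection noise for rendered images.

    Expected photon counts are ``photon_scale * dye_amount`` per lysosome plus
    a planar background; shot noise is Poisson on the expected counts, then
    additive Gaussian read noise, clipped at zero.
    """

    background_level: float = 50.0
    gradient_amplitude: float = 20.0
    read_noise_sd: float = 3.0
    photon_scale: float = 1.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_level", "gradient_amplitude", "read_noise_sd", "photon_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def noiseless(cls, photon_scale: float = 1.0) -> "NoiseModel":
        """Zero background, zero read noise, shot noise disabled."""
        return cls(
            background_level=0.0,
            gradient_amplitude=0.0,
            read_noise_sd=0.0,
            photon_scale=photon_scale,
            shot_noise=False,
            seed=0,
        )


@dataclass(frozen=True)
class Cell:
    """Elliptical cell footprint used only to group lysosomes."""

    cell_id: int
    center: tuple[float, float]      # (row, col), px
    semi_axes: tuple[float, float]   # (row, col), px

    def contains(self, row: float, col: float, shrink: float = 1.0) -> bool:
        a, b = self.semi_axes
        dr = (row - self.center[0]) / (a * shrink)
        dc = (col - self.center[1]) / (b * shrink)
        return dr * dr + dc * dc <= 1.0


@dataclass(frozen=True)
class Lysosome:
    cell_id: int
    lysosome_id: int
    row: float
    col: float
    radius_px: float     # Gaussian sigma of the rendered spot
    dye_amount: float
    true_ph: float


@dataclass(frozen=True)
class SyntheticScene:
    """Ground truth for one rendered field of view."""

    image_shape: tuple[int, int]
    pixel_size_um: float
    cells: tuple[Cell, ...]
    lysosomes: tuple[Lysosome, ...]
    law: GroundTruthLaw
    condition_label: str = ""

    def __post_init__(self) -> None:
        cells_by_id = {c.cell_id: c for c in self.cells}
        ids = [l.lysosome_id for l in self.lysosomes]
        if len(ids) != len(set(ids)):
            raise ValueError("lysosome ids must be unique")
        for lys in self.lysosomes:
            if not (PH_BOUNDS[0] <= lys.true_ph <= PH_BOUNDS[1]):
                raise ValueError("true_ph outside physical bounds")
            cell = cells_by_id.get(lys.cell_id)
            if cell is None or not cell.contains(lys.row, lys.col):
                raise ValueError("lysosome center outside its cell mask")

    def cell_label_mask(self) -> np.ndarray:
        """Integer label image: 0 background, cell_id elsewhere."""
        rr, cc = np.mgrid[0 : self.image_shape[0], 0 : self.image_shape[1]]
        mask = np.zeros(self.image_shape, dtype=np.int32)
        for cell in self.cells:
            a, b = cell.semi_axes
            inside = ((rr - cell.center[0]) / a) ** 2 + ((cc - cell.center[1]) / b) ** 2 <= 1.0
            mask[inside] = cell.cell_id
        return mask


@dataclass(frozen=True)
class ImagePair:
    """Matched 445/488 nm excitation images of one field (same shape)."""

    ch445: np.ndarray
    ch488: np.ndarray
    pixel_size_um: float
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ch445.shape != self.ch488.shape:
            raise ValueError("channel shapes differ")
        if np.any(self.ch445 < 0) or np.any(self.ch488 < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the scene generator.

    ``pixel_size_um`` has no default on purpose: the camera/objective
    magnification is an acquisition property the analysis cannot infer.
    Radius and dye amount are log-normal (median, log-sd); true pH is Normal
    truncated to the physical bounds.
    """

    pixel_size_um: float
    image_shape: tuple[int, int] = (256, 256)
    n_cells: int = 1
    lysosomes_per_cell: int = 25
    radius_px_median: float = 2.0
    radius_px_sigma: float = 0.25
    dye_median: float = 3000.0
    dye_sigma: float = 0.3
    ph_mean: float = 4.32
    ph_sd: float = 0.15
    law: GroundTruthLaw = GroundTruthLaw()
    condition_label: str = "control"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if len(self.image_shape) != 2 or min(self.image_shape) <= 0:
            raise ValueError("image_shape must be positive (rows, cols)")
        if self.n_cells < 0 or self.lysosomes_per_cell < 0:
            raise ValueError("counts must be non-negative")
        if self.radius_px_median <= 0 or self.radius_px_sigma <= 0:
            raise ValueError("radius distribution parameters must be positive")
        if self.dye_median <= 0 or self.dye_sigma <= 0 or self.ph_sd <= 0:
            raise ValueError("distribution dispersion parameters must be positive")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    # Rejection sampling keeps the draw stream simple and exactly reproducible.
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated normal rejection failed; check bounds")


def _layout_cells(cfg: SceneConfig, rng: np.random.Generator) -> tuple[Cell, ...]:
    """Non-overlapping ellipses on a jittered grid."""
    n = cfg.n_cells
    if n == 0:
        return ()
    nrows = max(1, int(math.floor(math.sqrt(n))))
    ncols = int(math.ceil(n / nrows))
    box_h = cfg.image_shape[0] / nrows
    box_w = cfg.image_shape[1] / ncols
    cells = []
    for k in range(n):
        i, j = divmod(k, ncols)
        cr = (i + 0.5) * box_h + rng.uniform(-0.04, 0.04) * box_h
        cc = (j + 0.5) * box_w + rng.uniform(-0.04, 0.04) * box_w
        a = 0.38 * box_h * rng.uniform(0.9, 1.1)
        b = 0.38 * box_w * rng.uniform(0.9, 1.1)
        cells.append(Cell(cell_id=k + 1, center=(cr, cc), semi_axes=(a, b)))
    return tuple(cells)


def make_scene(cfg: SceneConfig, seed: int) -> SyntheticScene:
    """Draw a ground-truth scene: cell layout, then lysosomes per cell.

    Deterministic for a fixed seed.  Geometry (cell layout, positions, radii,
    dye amounts) and true pH values are drawn from two separate child streams
    of ``seed`` so that the pH draws can be reproduced independently.
    """
    geom_rng = np.random.default_rng([seed, 0])
    ph_rng = np.random.default_rng([seed, 1])
    cells = _layout_cells(cfg, geom_rng)
    lysosomes = []
    lid = 0
    for cell in cells:
        a, b = cell.semi_axes
        for _ in range(cfg.lysosomes_per_cell):
            while True:  # uniform in the shrunken ellipse
                u = geom_rng.uniform(-1.0, 1.0)
                v = geom_rng.uniform(-1.0, 1.0)
                if u * u + v * v <= 1.0:
                    break
            row = cell.center[0] + 0.85 * a * u
            col = cell.center[1] + 0.85 * b * v
            radius = cfg.radius_px_median * math.exp(geom_rng.normal(0.0, cfg.radius_px_sigma))
            dye = cfg.dye_median * math.exp(geom_rng.normal(0.0, cfg.dye_sigma))
            ph = _truncated_normal(ph_rng, cfg.ph_mean, cfg.ph_sd, *PH_BOUNDS)
            lid += 1
            lysosomes.append(
                Lysosome(cell_id=cell.cell_id, lysosome_id=lid, row=row, col=col,
                         radius_px=radius, dye_amount=dye, true_ph=ph)
            )
    return SyntheticScene(
        image_shape=tuple(cfg.image_shape),
        pixel_size_um=cfg.pixel_size_um,
        cells=cells,
        lysosomes=tuple(lysosomes),
        law=cfg.law,
        condition_label=cfg.condition_label,
    )


def _expected_channels(scene: SyntheticScene, noise: NoiseModel) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expected count maps for both channels (spots only, no background)."""
    h, w = scene.image_shape
    e445 = np.zeros((h, w), dtype=float)
    e488 = np.zeros((h, w), dtype=float)
    for lys in scene.lysosomes:
        sigma = lys.radius_px
        ext = int(math.ceil(3.0 * sigma))
        r0 = max(0, int(math.floor(lys.row)) - ext)
        r1 = min(h, int(math.ceil(lys.row)) + ext + 1)
        c0 = max(0, int(math.floor(lys.col)) - ext)
        c1 = min(w, int(math.ceil(lys.col)) + ext + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1, dtype=float)[:, None] - lys.row
        cc = np.arange(c0, c1, dtype=float)[None, :] - lys.col
        d2 = rr * rr + cc * cc
        g = np.exp(-d2 / (2.0 * sigma * sigma))
        g[d2 > (3.0 * sigma) ** 2] = 0.0  # truncate at 3 sigma
        amp = noise.photon_scale * lys.dye_amount
        e445[r0:r1, c0:c1] += amp * g
        e488[r0:r1, c0:c1] += amp * scene.law.ratio(lys.true_ph) * g
    return e445, e488


def _background(shape: tuple[int, int], noise: NoiseModel) -> np.ndarray:
    h, w = shape
    rr = np.arange(h, dtype=float)[:, None]
    cc = np.arange(w, dtype=float)[None, :]
    denom = max(h + w - 2, 1)
    return noise.background_level + noise.gradient_amplitude * (rr + cc) / denom


def render_image_pair(scene: SyntheticScene, noise: NoiseModel) -> ImagePair:
    """Render the two excitation channels of a scene under a noise model.

    Expected signal: ch445 = photon_scale * dye * G(x), ch488 the same scaled
    by R(true_ph); plus a planar background.  Shot noise (Poisson) and read
    noise (Gaussian) applied when enabled, result clipped at 0.  Deterministic
    for a fixed ``noise.seed``.
    """
    e445, e488 = _expected_channels(scene, noise)
    bg = _background(scene.image_shape, noise)
    exp445 = e445 + bg
    exp488 = e488 + bg
    rng = np.random.default_rng(noise.seed)
    if noise.shot_noise:
        img445 = rng.poisson(exp445).astype(float)
        img488 = rng.poisson(exp488).astype(float)
    else:
        img445 = exp445
        img488 = exp488
    if noise.read_noise_sd > 0:
        img445 = img445 + rng.normal(0.0, noise.read_noise_sd, img445.shape)
        img488 = img488 + rng.normal(0.0, noise.read_noise_sd, img488.shape)
    img445 = np.clip(img445, 0.0, None)
    img488 = np.clip(img488, 0.0, None)
    labels = {"condition": scene.condition_label,
              "cell_ids": [c.cell_id for c in scene.cells]}
    return ImagePair(ch445=img445, ch488=img488,
                     pixel_size_um=scene.pixel_size_um, labels=labels)


def _clamp_scene_ph(scene: SyntheticScene, buffer_ph: float) -> SyntheticScene:
    """Force every lysosome to the buffer pH (ionophore clamp emulation)."""
    clamped = tuple(replace(l, true_ph=float(buffer_ph)) for l in scene.lysosomes)
    return replace(scene, lysosomes=clamped,
                   condition_label=f"calib_ph{buffer_ph:g}")


def make_calibration_series(
    scene_cfg: SceneConfig,
    buffer_phs: Sequence[float] = DEFAULT_BUFFER_PHS,
    cells_per_buffer: int = 4,
    law: GroundTruthLaw | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> list[tuple[float, list[tuple[SyntheticScene, ImagePair]]]]:
    """Render the ionophore-clamped calibration series.

    One single-cell image pair per cell, ``cells_per_buffer`` cells per buffer.
    Every lysosome's true pH equals the buffer pH.  Buffer pH values must be
    strictly monotone (hence free of duplicates).
    """
    buffer_phs = list(buffer_phs)
    if not buffer_phs:
        raise ValueError("buffer_phs must be non-empty")
    diffs = np.diff(buffer_phs)
    if len(buffer_phs) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("buffer_phs must be strictly increasing or decreasing")
    if cells_per_buffer < 1:
        raise ValueError("cells_per_buffer must be >= 1")
    if law is not None:
        scene_cfg = replace(scene_cfg, law=law)
    scene_cfg = replace(scene_cfg, n_cells=1)

    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31, size=2 * len(buffer_phs) * cells_per_buffer)
    series = []
    k = 0
    for buffer_ph in buffer_phs:
        group = []
        for _ in range(cells_per_buffer):
            scene = make_scene(scene_cfg, seed=int(sub_seeds[k]))
            scene = _clamp_scene_ph(scene, buffer_ph)
            pair = render_image_pair(scene, replace(noise, seed=int(sub_seeds[k + 1])))
            group.append((scene, pair))
            k += 2
        series.append((float(buffer_ph), group))
    return series


# ---------------------------------------------------------------------------
# File output: 16-bit grayscale TIFF per channel + plain-text ground truth.

def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def write_image_pair(pair: ImagePair, outdir: Path, condition: str, cell_id: int) -> list[Path]:
    """Write `{condition}__cell{ID}__{445|488}.tif` (16-bit grayscale)."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for chan, img in (("445", pair.ch445), ("488", pair.ch488)):
        p = outdir / f"{condition}__cell{cell_id}__{chan}.tif"
        tifffile.imwrite(p, _to_uint16(img))
        paths.append(p)
    return paths


def _truth_rows(scene: SyntheticScene, scene_name: str) -> list[dict]:
    return [
        {
            "scene": scene_name,
            "cell_id": l.cell_id,
            "lysosome_id": l.lysosome_id,
            "row": l.row,
            "col": l.col,
            "radius_px": l.radius_px,
            "true_ph": l.true_ph,
        }
        for l in scene.lysosomes
    ]


def write_condition_images(
    scenes_and_pairs: Sequence[tuple[SyntheticScene, ImagePair]],
    outdir: Path,
    noise: NoiseModel,
    seed: int,
) -> None:
    """Write per-cell TIFFs plus `truth_lysosomes.csv` and `generator.json`."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    law = None
    for idx, (scene, pair) in enumerate(scenes_and_pairs):
        law = scene.law
        name = f"{scene.condition_label}__cell{idx + 1}"
        write_image_pair(pair, outdir, scene.condition_label, idx + 1)
        for r in _truth_rows(scene, name):
            rows.append(r)
    pd.DataFrame(rows).to_csv(outdir / "truth_lysosomes.csv", index=False)
    meta = {
        "law": dataclasses.asdict(law) if law is not None else None,
        "noise": dataclasses.asdict(noise),
        "seed": int(seed),
    }
    (outdir / "generator.json").write_text(json.dumps(meta, indent=2))


def write_calibration_series(
    series: Sequence[tuple[float, Sequence[tuple[SyntheticScene, ImagePair]]]],
    outdir: Path,
) -> None:
    """Write calibration image pairs as `calib_ph{X}__cell{ID}__{chan}.tif`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for buffer_ph, group in series:
        for j, (_scene, pair) in enumerate(group):
            write_image_pair(pair, outdir, f"calib_ph{buffer_ph:g}", j + 1)
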