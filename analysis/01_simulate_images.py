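#!/usr/bin/env python
"""Render the synthetic imaging dataset: per-cell 445/488 nm TIFF pairs for a
control-vs-treated experiment plus the ionophore-clamped calibration series,
with ground truth alongside (truth_lysosomes.csv, generator.json).

Writes results/synthetic_images/.  Everything downstream (02_quantify_ph.py,
or `lysoquant quantify --indir`) can start from these files.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import numpy as np

from lysoquant.pipeline_io import QuantifyConfig
from lysoquant.synth_imaging import (
    SceneConfig,
    make_calibration_series,
    make_scene,
    render_image_pair,
    write_calibration_series,
    write_condition_images,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path,
                        default=Path("results/synthetic_images"))
    args = parser.parse_args()

    cfg = QuantifyConfig(seed=args.seed)
    rng = np.random.default_rng(cfg.seed)
    scenes_and_pairs = []
    for cond in cfg.conditions:
        scene_cfg = SceneConfig(
            pixel_size_um=cfg.pixel_size_um, image_shape=cfg.image_shape,
            n_cells=1, lysosomes_per_cell=cfg.lysosomes_per_cell,
            radius_px_median=cond.radius_px_median, ph_mean=cond.ph_mean,
            ph_sd=cond.ph_sd, law=cfg.law, condition_label=cond.label,
        )
        for _ in range(cfg.cells_per_condition):
            s1, s2 = (int(v) for v in rng.integers(0, 2**31, size=2))
            scene = make_scene(scene_cfg, seed=s1)
            pair = render_image_pair(scene, replace(cfg.noise, seed=s2))
            scenes_and_pairs.append((scene, pair))
    write_condition_images(scenes_and_pairs, args.outdir, cfg.noise, cfg.seed)

    calib_cfg = SceneConfig(
        pixel_size_um=cfg.pixel_size_um, image_shape=cfg.calib_image_shape,
        n_cells=1, lysosomes_per_cell=cfg.calib_lysosomes_per_cell, law=cfg.law,
    )
    series = make_calibration_series(
        calib_cfg, buffer_phs=cfg.buffer_phs, cells_per_buffer=cfg.cells_per_buffer,
        noise=cfg.noise, seed=int(rng.integers(0, 2**31)),
    )
    write_calibration_series(series, args.outdir)

    n_calib = sum(len(g) for _, g in series)
    n_lys = sum(len(s.lysosomes) for s, _ in scenes_and_pairs)
    print(f"wrote {len(scenes_and_pairs)} condition cells ({n_lys} lysosomes) "
          f"and {n_calib} calibration cells across {len(series)} buffers "
          f"to {args.outdir}")
    print(f"ground-truth ratio law: pKa {cfg.law.ph50}, floor {cfg.law.r_min}, "
          f"ceiling {cfg.law.r_max}")


if __name__ == "__main__":
    main()
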