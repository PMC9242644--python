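#!/usr/bin/env python
"""Quantify break-in inhibition of the simulated transporter current.

Three batches of simulated whole-cell recordings, each cell measured 30 s
(baseline) and 3 min (developed dialysis) after break-in:

  * no lipid in the pipette      -> stability control, ratios ~ 1
  * 100 uM inhibitory lipid      -> steady-state and tail inhibition
  * lipid-insensitive transporter (inhibition ceiling 0, Y715C-like)
    at 100 uM                    -> ratios ~ 1 again

Writes family_metrics.csv and inhibition_ratios.csv per batch under
results/ephys/ and prints the mean ratios with the implied % inhibition.
"""

import argparse
from dataclasses import replace
from pathlib import Path

from lysoquant.ephys import InhibitionModel
from lysoquant.pipeline_io import EphysConfig, run_ephys


def run_batch(name: str, cfg: EphysConfig, outdir: Path) -> None:
    result = run_ephys(cfg, outdir=outdir / name)
    mr = result.ratios["max_ratio"].mean()
    tr = result.ratios["tail_ratio"].mean()
    print(f"  {name:12s} ({cfg.n_cells} cells, {cfg.conc_um:g} uM): "
          f"max ratio {mr:.3f} ({100 * (1 - mr):+.1f}% change), "
          f"tail ratio {tr:.3f} ({100 * (1 - tr):+.1f}% change)")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/ephys"))
    args = parser.parse_args()

    base = EphysConfig(seed=args.seed, n_cells=10, dose_concentrations_um=())
    print("3 min / 30 s current ratios at +140 mV:")
    run_batch("stability", replace(base, conc_um=0.0), args.outdir)
    run_batch("lipid_100um", replace(base, conc_um=100.0), args.outdir)
    insensitive = InhibitionModel(f_ceiling=0.0, f_ceiling_tail=0.0)
    run_batch("insensitive", replace(base, conc_um=100.0, inhibition=insensitive),
              args.outdir)


if __name__ == "__main__":
    main()
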