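#!/usr/bin/env python
"""Deconvolve hotspot coverage to DSB-relative binding profiles.

Finds the spatial anatomy of the ssDNA-bound proteins: DMC1 peaks right at
the break with a long distal tail, RAD51 sits distally near the
ssDNA/dsDNA junction with its mode above its median, and repair-template
RPA (the D-loop signature) straddles the break.
"""

import json
import sys
from pathlib import Path

from meiomap.kernels import default_kernel
from meiomap.pipeline import RunConfig, run_pipeline
from meiomap.synthetic import GeneratorConfig

OUT = Path("results/02_deconvolution")


def main(seed: int = 1) -> None:
    cfg = RunConfig(generator=GeneratorConfig(seed=seed), out_dir=str(OUT),
                    seed=seed, stages=("simulate", "deconvolve"))
    run_pipeline(cfg)
    summary = json.loads((OUT / "deconvolve_summary.json").read_text())
    print(f"{'track':14} {'peak bp':>8} {'median bp':>10} {'central 95%':>20}")
    for name, st in summary.items():
        lo, hi = st["central95"]
        print(f"{name:14} {st['peak_bp']:8.0f} {st['median_bp']:10.0f} "
              f"{f'{lo:.0f}..{hi:.0f}':>20}")
    for prot in ("DMC1", "RAD51", "RPA_TEMPLATE"):
        m = default_kernel(prot).measured_stats()
        rec = summary[prot]
        print(f"{prot}: recovered mode {rec['peak_bp']:.0f} bp vs noise-free "
              f"measurement truth {m['peak_bp']:.0f} bp")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
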