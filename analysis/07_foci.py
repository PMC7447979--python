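#!/usr/bin/env python
"""Quantify RAD51/DMC1 focus geometry on chromosome spreads.

Measures focus-to-axis distances per channel, pairs co-foci across channels
at the 300 nm threshold, compares axis proximity (RAD51 generated closer to
axes than DMC1), and tests whether far-off-axis RAD51 foci look like
uniform background.
"""

import json
import sys
from pathlib import Path

from meiomap.pipeline import RunConfig, run_pipeline
from meiomap.synthetic import GeneratorConfig

OUT = Path("results/07_foci")


def main(seed: int = 1) -> None:
    gen = GeneratorConfig(seed=seed, n_cells=20, pairs_per_cell=150)
    cfg = RunConfig(generator=gen, out_dir=str(OUT), seed=seed,
                    stages=("simulate", "foci"))
    run_pipeline(cfg)
    f = json.loads((OUT / "foci_summary.json").read_text())
    print(f"median axis distance: RAD51 {f['median_axis_distance_rad51']:.0f} nm, "
          f"DMC1 {f['median_axis_distance_dmc1']:.0f} nm "
          f"(Welch t p = {f['axis_proximity_p']:.2g})")
    print(f"co-focus fractions at 300 nm: RAD51 "
          f"{100*f['cofocus_fraction_rad51']:.0f}%, DMC1 "
          f"{100*f['cofocus_fraction_dmc1']:.0f}%; median pair offset "
          f"{f['median_pair_offset_nm']:.0f} nm")
    u = f["offaxis_uniformity"]
    if "p" in u:
        print(f"off-axis (>450 nm) uniformity: KS p = {u['p']:.3g} on n={u['n']} "
              f"(rejected here because axis-associated foci near curved axes "
              f"also reach the far field; a background-only control calibrates "
              f"to uniform)")
    else:
        print(f"off-axis uniformity not testable here: {u.get('error')}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
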