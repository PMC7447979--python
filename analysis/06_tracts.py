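#!/usr/bin/env python
"""Map gene-conversion tracts from SNP-censored records.

Builds the per-bp crossover breakpoint probability map from informative-SNP
intervals, deconvolves it to DSB-relative coordinates, converts it into the
probability that a position is contained in a crossover conversion tract
(tracts assumed to overlap the break), and builds the equal-weight
non-crossover tract map.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from meiomap.binstats import binned_quantiles
from meiomap.pipeline import RunConfig, run_pipeline
from meiomap.synthetic import GeneratorConfig

OUT = Path("results/06_tracts")


def main(seed: int = 1) -> None:
    cfg = RunConfig(generator=GeneratorConfig(seed=seed), out_dir=str(OUT),
                    seed=seed, stages=("simulate", "tracts"))
    run_pipeline(cfg)
    s = json.loads((OUT / "tracts_summary.json").read_text())
    print(f"{s['n_crossovers']} crossovers mapped ({s['n_clipped']} clipped at "
          f"±2 kb), {s['n_ncos']} non-crossovers ({s['n_nco_excluded']} beyond "
          f"2 kb excluded)")
    cont = pd.read_csv(OUT / "co_tract_containment.tsv", sep="\t")
    mass = np.clip(cont.iloc[:, 1].to_numpy(), 0, None)
    med, lo, hi = binned_quantiles(mass, k_lo=-50, qs=[0.5, 0.025, 0.975])
    print(f"crossover tract containment: central 95% spans {lo:.0f}..{hi:.0f} bp "
          f"around the break")
    nco = pd.read_csv(OUT / "nco_tract_map.tsv", sep="\t")
    nmass = np.clip(nco.iloc[:, 1].to_numpy(), 0, None)
    nmed, nlo, nhi = binned_quantiles(nmass, k_lo=-50, qs=[0.5, 0.25, 0.75])
    print(f"non-crossover tract mass: interquartile span {nlo:.0f}..{nhi:.0f} bp; "
          f"the underlying tracts are short (mean 150 bp) but the tol-0.2 "
          f"deconvolution smears the narrow map")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
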