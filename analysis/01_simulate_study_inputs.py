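#!/usr/bin/env python
"""Generate the synthetic study inputs every later stage consumes.

Emulates the structure of the real study: a set of candidate phylogenies,
a species × trait table evolved under the allometric model with one
planted "exceptional" species (an enlarged olfactory bulb on the log
scale), a two-species specimen table, and a sectioned 3-D cell field.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from phyloallometry import (SimulationConfig, simulate_allometric_traits,
                            simulate_cell_field, simulate_tree_set,
                            simulate_two_species_specimens, write_tree_set)

N_TREES = 100          # candidate phylogenies (a scaled-down tree set)
N_TIPS = 80            # species in the comparative dataset
OUTLIER = "sp040"      # the planted exceptional species
OUTLIER_SD = 5.0       # planted offset, in residual SDs


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/inputs"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed, n_tips=N_TIPS,
                           outlier_species=OUTLIER)
    trees = simulate_tree_set(cfg, N_TREES)
    write_tree_set(trees, str(args.out / "trees.nwk"))

    offset = OUTLIER_SD * np.sqrt(cfg.sigma2 * trees[0].height)
    cfg = SimulationConfig(seed=args.seed, n_tips=N_TIPS,
                           outlier_species=OUTLIER, outlier_offset=offset)
    traits = simulate_allometric_traits(trees[0], cfg)
    traits.write(str(args.out / "traits.csv"))

    specimens = simulate_two_species_specimens(cfg)
    specimens.to_csv(args.out / "specimens.tsv", sep="\t", index=False)

    # a mitral-cell-scale field: ~1e5 cells in a 1 mm-radius bulb gives a
    # raw tally of several hundred under the every-10th 70x70/250x250 design
    field_cfg = SimulationConfig(seed=args.seed, true_n=100_000,
                                 field_radius_um=1000.0)
    field = simulate_cell_field(field_cfg)
    pd.DataFrame({"section": np.arange(len(field.tallies)),
                  "tally": field.tallies}).to_csv(
        args.out / "tallies.tsv", sep="\t", index=False)

    print(f"{N_TREES} trees ({N_TIPS} tips), traits with {OUTLIER} shifted "
          f"+{offset:.3f} log10 units (+{OUTLIER_SD} residual SD), "
          f"{len(specimens)} specimens, {len(field.tallies)} counted "
          f"sections -> {args.out}")


if __name__ == "__main__":
    main()
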