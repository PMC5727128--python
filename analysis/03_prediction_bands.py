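#!/usr/bin/env python
"""Draw the phylogeny-aware 95% prediction band around the olfactory-bulb
allometry and flag species falling outside it; the planted exceptional
species should be the one sitting above the band."""

import argparse
from pathlib import Path

import numpy as np

from phyloallometry import (TraitTable, fit_pgls, flag_outliers,
                            prediction_band, read_tree_set)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", type=Path, default=Path("results/inputs"))
    ap.add_argument("--fits", type=Path, default=Path("results/fits"))
    ap.add_argument("--out", type=Path, default=Path("results/bands"))
    ap.add_argument("--level", type=float, default=0.95)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    consensus = read_tree_set(str(args.fits / "consensus.nwk"))[0]
    traits = TraitTable.read(str(args.inputs / "traits.csv"))
    fit = fit_pgls(consensus, traits, "olfactory_bulb", "whole_brain",
                   lam="ML", intersect=True)
    grid = np.linspace(fit.x.min() - 0.25, fit.x.max() + 0.25, 101)
    band = prediction_band(fit, grid, level=args.level)
    band.to_frame().to_csv(args.out / "band.tsv", sep="\t", index=False,
                           float_format="%.8g")
    flags = flag_outliers(fit, traits, band)
    flags.to_csv(args.out / "outliers.tsv", sep="\t", index=False,
                 float_format="%.8g")
    outside = flags[~flags["inside"]]
    print(f"slope {fit.slope:.4f}, lambda {fit.lam:.3f}; "
          f"{len(outside)}/{len(flags)} species outside the "
          f"{args.level:.0%} band:")
    print(outside[["species", "status",
                   "deviation_bandwidths"]].to_string(index=False))


if __name__ == "__main__":
    main()
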