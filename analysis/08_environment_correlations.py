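"""Correlate diversity dynamics with environmental/sampling series.

Pairwise correlations after generalized differencing, and AR(1)-GLS model
comparison by AICc with Akaike weights, run on the full bin window and on a
truncated window excluding the terminal bin (to ask how much the final
extinction drives the correlations).
"""

from pathlib import Path

import pandas as pd

from cladewane.strat import read_bins, read_ranges
from cladewane.trees import read_trees
from cladewane.timescale import timescale_set
from cladewane.diversity import phylo_diversity
from cladewane.envcorr import run_windows

SYN = Path("results/synthetic")
OUT = Path("results")


def main() -> None:
    ranges = read_ranges(SYN / "ranges.csv")
    bins = read_bins(SYN / "bins.csv")
    trees = timescale_set(read_trees(SYN / "cladogram.nwk"), ranges,
                          ("basic", "equal"))
    pde = phylo_diversity(trees, ranges, bins)
    env = pd.read_csv(SYN / "env.csv").set_index("bin")
    occ = pd.read_csv(SYN / "occurrences.csv").set_index("bin")

    response = pd.Series(pde.values, index=bins.names, name="pde")
    predictors = env.join(occ[["n_group_formations"]])
    times = pd.Series(bins.midpoints, index=bins.names)
    windows = {"full": bins.names, "no_terminal": bins.names[:-1]}
    res = run_windows(response, predictors, times, windows)

    pairwise_rows = []
    for wname, r in res.items():
        if r.get("skipped"):
            print(f"{wname}: skipped ({r['reason']})")
            continue
        r["models"].to_csv(OUT / f"models_{wname}.csv", index=False)
        for pred, pr in r["pairwise"].items():
            pairwise_rows.append((wname, pred, pr["r"], pr["p"]))
        best = r["models"].iloc[0]
        print(f"{wname}: best model {best['model']!r} "
              f"(AICc {best['aicc']:.1f}, weight {best['weight']:.2f})")
    pd.DataFrame(pairwise_rows, columns=["window", "predictor", "r", "p"]
                 ).to_csv(OUT / "pairwise_correlations.csv", index=False)


if __name__ == "__main__":
    main()
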