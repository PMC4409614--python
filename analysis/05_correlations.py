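"""Spearman correlations among and between the centrality measures.

Within each age level: binary vs weighted per measure and the documented
pairs among the binary measures.  Between consecutive age levels
(weaned-growing, growing-gilt): each measure correlated across the animals
tracked at both levels.  Writes results/correlations_within.csv and
results/correlations_cross.csv.
"""

from pathlib import Path

import pandas as pd

from agonet.events import read_trajectories
from agonet.stats import (
    correlations_to_frame,
    cross_level_correlations,
    within_level_correlations,
)


def main() -> None:
    records = pd.read_csv("results/centrality.csv")
    trajectories = read_trajectories("results/study/trajectories.csv")

    within = [
        r
        for level in ("weaned", "growing", "gilt")
        for r in within_level_correlations(records, level)
    ]
    cross = cross_level_correlations(records, trajectories)
    correlations_to_frame(within).to_csv("results/correlations_within.csv", index=False)
    correlations_to_frame(cross).to_csv("results/correlations_cross.csv", index=False)

    print(f"{len(within)} within-level and {len(cross)} cross-level correlations written")
    print("binary vs weighted degree per level:")
    for r in within:
        if (r.var_x, r.var_y) == ("degree_binary", "degree_weighted"):
            print(f"  {r.context:<8} rho = {r.rho:.2f} (n = {r.n})")
    print("consecutive-level out-degree carry-over:")
    for r in cross:
        if r.var_x == "out_degree_weighted":
            star = "*" if r.significant else ""
            print(f"  {r.context:<16} rho = {r.rho:.2f}{star} (n = {r.n})")


if __name__ == "__main__":
    main()
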