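"""Compare every centrality measure across the three age levels.

Kruskal-Wallis test per measure with pairwise significance letters
(groups not sharing a letter differ at p < 0.05).  Writes
results/summary_levels.csv and prints the median (range) table.
"""

from pathlib import Path

import pandas as pd

from agonet.stats import level_comparison_table

OUT = Path("results/summary_levels.csv")


def main() -> None:
    records = pd.read_csv("results/centrality.csv")
    summary, results = level_comparison_table(records)
    summary.to_csv(OUT, index=False)

    print(f"level comparison written to {OUT}")
    print(f"{'measure':<22}{'weaned':>18}{'growing':>18}{'gilt':>18}   KW p")
    for measure, res in results.items():
        cells = []
        for level in ("weaned", "growing", "gilt"):
            _, med, lo, hi = res.summaries[level]
            cells.append(f"{med:.2f}^{res.letters[level]} ({lo:.2f}-{hi:.2f})")
        print(f"{measure:<22}{cells[0]:>18}{cells[1]:>18}{cells[2]:>18}   {res.p_formatted}")


if __name__ == "__main__":
    main()
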