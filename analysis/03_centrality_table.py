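"""Compute all 14 centrality measures for every animal.

Degree, in-degree, out-degree, betweenness, closeness, ingoing and
outgoing closeness — binary and weighted — with weighted path lengths
1/weight and component-scaled closeness.  Writes results/centrality.csv
and prints the per-level medians of the headline measures.
"""

from pathlib import Path

from agonet.centrality import centrality_table
from agonet.events import filter_events, read_events, read_roster
from agonet.network import build_network

STUDY = Path("results/study")
OUT = Path("results/centrality.csv")


def main() -> None:
    events = filter_events(read_events(STUDY / "events.csv"))
    rosters = read_roster(STUDY / "roster.csv")
    by_pen: dict[tuple, list] = {}
    for ev in events:
        by_pen.setdefault((ev.pen_id, ev.age_level), []).append(ev)
    nets = [build_network(by_pen.get((r.pen_id, r.age_level), []), r) for r in rosters]
    records = centrality_table(nets)
    records.to_csv(OUT, index=False)

    print(f"{len(records)} animal records written to {OUT}")
    medians = records.groupby("age_level")[
        ["degree_binary", "degree_weighted", "closeness_binary", "betweenness_binary"]
    ].median()
    print("per-level medians:")
    print(medians.loc[["weaned", "growing", "gilt"]].round(3))


if __name__ == "__main__":
    main()
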