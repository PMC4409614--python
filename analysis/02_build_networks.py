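"""Build the per-pen directed weighted fight networks and export them.

Reads results/study/, aggregates each pen's events (clear fight: weight 1
initiator->receiver; stand-off: 0.5 per direction), verifies the exact
conservation identity (total edge weight == event count), and writes every
network as edge-list CSV and GraphML under results/networks/.
"""

from pathlib import Path

from agonet.events import filter_events, read_events, read_roster
from agonet.network import build_network, write_edge_csv, write_graphml

STUDY = Path("results/study")
OUT = Path("results/networks")


def main() -> None:
    events = filter_events(read_events(STUDY / "events.csv"))
    rosters = read_roster(STUDY / "roster.csv")
    by_pen: dict[tuple, list] = {}
    for ev in events:
        by_pen.setdefault((ev.pen_id, ev.age_level), []).append(ev)

    OUT.mkdir(parents=True, exist_ok=True)
    total_weight = 0.0
    for roster in rosters:
        pen_events = by_pen.get((roster.pen_id, roster.age_level), [])
        net = build_network(pen_events, roster)
        assert net.total_weight == len(pen_events), "conservation identity violated"
        total_weight += net.total_weight
        write_edge_csv(net, OUT / f"{net.pen_id}.csv")
        write_graphml(net, OUT / f"{net.pen_id}.graphml")

    print(f"built {len(rosters)} networks; total edge weight {total_weight:g} "
          f"== {len(events)} events (conserved)")
    print(f"exports written to {OUT}/")


if __name__ == "__main__":
    main()
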