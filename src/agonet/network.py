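"""Per-pen directed weighted agonistic networks.

Each pen's fights are aggregated into one directed graph: a clear fight adds
weight 1 to the initiator->receiver edge; a stand-off (no identifiable
initiator) adds weight 0.5 to each of the two opposite edges.  Edge weights
are therefore multiples of 0.5 and are stored internally as integer
half-units so that conservation identities (total edge weight == number of
contributing events) hold exactly.

The full pen roster defines the node set, so animals that never fought are
isolated nodes with zero centrality downstream.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Iterator

from .events import AgeLevel, FightEvent, PenRoster, ValidationError


class PenNetwork:
    """Directed (or symmetric, after projection) weighted graph over a pen roster.

    Weights are kept in integer half-units; the public API reports floats.
    For an undirected network, edges are stored under a canonical
    (min, max) node ordering.
    """

    def __init__(
        self,
        pen_id: str,
        age_level: AgeLevel,
        nodes: Iterable[str],
        directed: bool = True,
    ) -> None:
        self.pen_id = pen_id
        self.age_level = age_level
        self.nodes: tuple[str, ...] = tuple(sorted(set(nodes)))
        self.directed = directed
        self._half: dict[tuple[str, str], int] = {}

    # -- construction -----------------------------------------------------

    def _key(self, u: str, v: str) -> tuple[str, str]:
        if u == v:
            raise ValidationError(f"self-loop on {u!r}")
        if not self.directed and u > v:
            u, v = v, u
        return (u, v)

    def add_half_weight(self, u: str, v: str, half_units: int) -> None:
        """Add ``half_units`` * 0.5 to the (u, v) edge weight."""
        if half_units <= 0:
            raise ValueError("half_units must be positive")
        node_set = set(self.nodes)
        if u not in node_set or v not in node_set:
            missing = u if u not in node_set else v
            raise ValidationError(f"animal {missing!r} is not on the roster of pen {self.pen_id!r}")
        key = self._key(u, v)
        self._half[key] = self._half.get(key, 0) + half_units

    # -- queries ----------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    def half_weight(self, u: str, v: str) -> int:
        return self._half.get(self._key(u, v), 0)

    def weight(self, u: str, v: str) -> float:
        return self.half_weight(u, v) / 2.0

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Edges in deterministic (sorted) order with float weights."""
        for (u, v) in sorted(self._half):
            yield u, v, self._half[(u, v)] / 2.0

    @property
    def n_edges(self) -> int:
        return len(self._half)

    @property
    def total_half_weight(self) -> int:
        return sum(self._half.values())

    @property
    def total_weight(self) -> float:
        """Sum of edge weights; equals the number of contributing events."""
        return self.total_half_weight / 2.0

    def successors(self, u: str) -> list[tuple[str, int]]:
        """Outgoing (neighbor, half-weight) pairs; for undirected nets, all neighbors."""
        out = []
        for (a, b), h in self._half.items():
            if a == u:
                out.append((b, h))
            elif not self.directed and b == u:
                out.append((a, h))
        return out

    def predecessors(self, u: str) -> list[tuple[str, int]]:
        if not self.directed:
            return self.successors(u)
        return [(a, h) for (a, b), h in self._half.items() if b == u]

    def adjacency(self, reverse: bool = False) -> dict[str, list[tuple[str, int]]]:
        """Full adjacency map node -> [(neighbor, half-weight)], deterministic order."""
        adj: dict[str, list[tuple[str, int]]] = {u: [] for u in self.nodes}
        for (a, b) in sorted(self._half):
            h = self._half[(a, b)]
            if self.directed:
                if reverse:
                    adj[b].append((a, h))
                else:
                    adj[a].append((b, h))
            else:
                adj[a].append((b, h))
                adj[b].append((a, h))
        return adj

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PenNetwork):
            return NotImplemented
        return (
            self.pen_id == other.pen_id
            and self.age_level == other.age_level
            and self.nodes == other.nodes
            and self.directed == other.directed
            and self._half == other._half
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "directed" if self.directed else "undirected"
        return (
            f"PenNetwork({self.pen_id!r}, {self.age_level.value}, n={self.n}, "
            f"{kind}, edges={self.n_edges}, total_weight={self.total_weight})"
        )


def build_network(events: Iterable[FightEvent], roster: PenRoster) -> PenNetwork:
    """Aggregate a pen's fight events into its directed weighted network.

    A clear fight contributes 1.0 to initiator->receiver; a stand-off
    contributes 0.5 to each direction.  Roster members with no events stay
    as isolated nodes.  All events must belong to the roster's pen and
    age level and involve roster members.
    """
    net = PenNetwork(roster.pen_id, roster.age_level, roster.members, directed=True)
    for ev in events:
        if ev.pen_id != roster.pen_id or ev.age_level != roster.age_level:
            raise ValidationError(
                f"event from pen {ev.pen_id!r}/{ev.age_level.value} does not match "
                f"roster {roster.pen_id!r}/{roster.age_level.value}"
            )
        if ev.standoff:
            net.add_half_weight(ev.animal_a, ev.animal_b, 1)
            net.add_half_weight(ev.animal_b, ev.animal_a, 1)
        else:
            net.add_half_weight(ev.animal_a, ev.animal_b, 2)
    return net


def binarize(net: PenNetwork) -> PenNetwork:
    """Replace every positive edge weight by 1 (presence/absence network)."""
    out = PenNetwork(net.pen_id, net.age_level, net.nodes, directed=net.directed)
    for (u, v), h in net._half.items():
        if h > 0:
            out._half[(u, v)] = 2
    return out


def undirected_projection(net: PenNetwork) -> PenNetwork:
    """Collapse the directed network onto an undirected one.

    The undirected weight of a dyad is the sum of the two directional
    weights, preserving the pair's total contact frequency (and hence total
    weight conservation).
    """
    out = PenNetwork(net.pen_id, net.age_level, net.nodes, directed=False)
    for (u, v), h in net._half.items():
        key = out._key(u, v)
        out._half[key] = out._half.get(key, 0) + h
    return out


# -- export / import ------------------------------------------------------

def write_edge_csv(net: PenNetwork, path: str | Path) -> None:
    """Edge list CSV: source,target,weight (weights printed as decimals)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        for u, v, w in net.edges():
            writer.writerow([u, v, f"{w:g}"])


def read_edge_csv(path: str | Path) -> list[tuple[str, str, float]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(("source", "target", "weight")) - set(reader.fieldnames):
            raise ValidationError(f"{path}: expected columns source,target,weight")
        return [(row["source"], row["target"], float(row["weight"])) for row in reader]


def write_graphml(net: PenNetwork, path: str | Path) -> None:
    """Write the network as GraphML with a double edge attribute ``weight``."""
    root = ET.Element("graphml", xmlns="http://graphml.graphdrawing.org/xmlns")
    ET.SubElement(
        root,
        "key",
        {"id": "w", "for": "edge", "attr.name": "weight", "attr.type": "double"},
    )
    graph = ET.SubElement(
        root,
        "graph",
        {
            "id": net.pen_id,
            "edgedefault": "directed" if net.directed else "undirected",
        },
    )
    for node in net.nodes:
        ET.SubElement(graph, "node", {"id": node})
    for i, (u, v, w) in enumerate(net.edges()):
        edge = ET.SubElement(graph, "edge", {"id": f"e{i}", "source": u, "target": v})
        data = ET.SubElement(edge, "data", {"key": "w"})
        data.text = f"{w:g}"
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(Path(path), encoding="unicode", xml_declaration=True)
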