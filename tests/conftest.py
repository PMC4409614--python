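"""Shared fixtures: tiny hand-built pens and random-network factories."""

from __future__ import annotations

import numpy as np
import pytest

from agonet.events import AgeLevel, FightEvent, PenRoster, StudyTime
from agonet.network import PenNetwork, build_network


def make_event(
    a: str,
    b: str,
    standoff: bool = False,
    pen_id: str = "P1",
    level: AgeLevel = AgeLevel.WEANED,
    time: str = "1:12:30:00",
    duration: int = 10,
) -> FightEvent:
    return FightEvent(pen_id, level, a, b, StudyTime.parse(time), duration, standoff)


@pytest.fixture
def small_roster() -> PenRoster:
    return PenRoster("P1", AgeLevel.WEANED, frozenset(["A", "B", "C", "D"]))


@pytest.fixture
def small_events() -> list[FightEvent]:
    # A->B twice, one stand-off A-B, one clear B->C; D never fights
    return [
        make_event("A", "B"),
        make_event("A", "B", time="1:13:00:00"),
        make_event("A", "B", standoff=True, time="1:14:00:00"),
        make_event("B", "C", time="2:08:00:00"),
    ]


@pytest.fixture
def small_network(small_events, small_roster) -> PenNetwork:
    return build_network(small_events, small_roster)


def random_network(
    rng: np.random.Generator,
    n: int,
    edge_p: float = 0.4,
    max_half: int = 6,
    pen_id: str = "R",
) -> PenNetwork:
    """Random directed network with half-integer weights in [0.5, max_half/2]."""
    nodes = [f"n{i}" for i in range(n)]
    net = PenNetwork(pen_id, AgeLevel.WEANED, nodes, directed=True)
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < edge_p:
                net.add_half_weight(u, v, int(rng.integers(1, max_half + 1)))
    return net


def adjacency_lengths(net: PenNetwork, weighted: bool, reverse: bool = False) -> dict:
    """Edge-length adjacency in the package's shortest-path convention."""
    adj = net.adjacency(reverse=reverse)
    if weighted:
        return {u: [(v, 2.0 / h) for v, h in nbrs] for u, nbrs in adj.items()}
    return {u: [(v, 1.0) for v, _ in nbrs] for u, nbrs in adj.items()}
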