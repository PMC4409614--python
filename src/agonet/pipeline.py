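"""End-to-end pipeline: events -> networks -> centrality -> rank statistics.

One call reads (or simulates) a study, builds the per-pen directed weighted
networks, computes the 14-measure centrality table, compares measures
across age levels with significance letters, computes within-level and
consecutive-level Spearman correlations, and exports per-pen timelines with
hourly fight counts.  Every artifact is a plain CSV / GraphML / YAML file
that the package's own readers can re-read, and a run log records the seed,
option values and input checksums so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .centrality import MEASURE_COLUMNS, centrality_table
from .events import (
    DEFAULT_WINDOWS,
    AnimalTrajectory,
    FightEvent,
    ObservationWindow,
    PenRoster,
    filter_events,
    read_events,
    read_roster,
    read_trajectories,
    write_events,
    write_roster,
    write_trajectories,
)
from .network import PenNetwork, build_network, write_edge_csv, write_graphml
from .simulate import SyntheticConfig, generate_study, hours_since_mixing
from .stats import (
    correlations_to_frame,
    cross_level_correlations,
    level_comparison_table,
    within_level_correlations,
)

logger = logging.getLogger("agonet")


@dataclass
class RunConfig:
    """Inputs and options of one pipeline run.

    Exactly one of (events/roster paths, simulate) must be provided.
    """

    out_dir: Path
    events_path: Path | None = None
    roster_path: Path | None = None
    trajectories_path: Path | None = None
    simulate: SyntheticConfig | None = None
    windows: Sequence[ObservationWindow] = DEFAULT_WINDOWS
    min_duration: int = 1
    weighted_distance: str = "inverse"
    closeness_scaling: str = "component"
    letters_alpha: float = 0.05
    standardize_degree: bool = False
    pen_median: bool = False
    bonferroni: bool = False

    def validate(self) -> None:
        has_files = self.events_path is not None and self.roster_path is not None
        if has_files == (self.simulate is not None):
            raise ValueError("provide either events+roster paths or a simulate config, not both")
        if self.weighted_distance != "inverse":
            raise ValueError("the only supported weighted-distance convention is 'inverse'")


@dataclass
class TimelineResult:
    """Chronological event table of one pen plus its per-hour fight counts."""

    pen_id: str
    table: pd.DataFrame
    hourly: pd.DataFrame


def timeline_export(
    events: Sequence[FightEvent],
    pen_id: str,
    windows: Sequence[ObservationWindow] = DEFAULT_WINDOWS,
) -> TimelineResult:
    """Chronologically sorted fight sequence of one pen.

    Stand-off events carry their participants as an unordered (sorted)
    pair with the standoff flag set; attacker/victim columns are only
    meaningful for clear fights.  The hourly table bins fights by whole
    hours since mixing and conserves the event total.
    """
    pen_events = sorted(
        (ev for ev in events if ev.pen_id == pen_id),
        key=lambda e: (e.start_time, e.animal_a, e.animal_b),
    )
    rows = []
    for ev in pen_events:
        a, b = ev.animal_a, ev.animal_b
        if ev.standoff:
            a, b = sorted((a, b))
        rows.append(
            {
                "pen_id": pen_id,
                "start_time": str(ev.start_time),
                "hours_since_mixing": hours_since_mixing(ev.start_time, windows),
                "attacker": a,
                "victim": b,
                "standoff": int(ev.standoff),
                "duration_s": ev.duration,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "pen_id",
            "start_time",
            "hours_since_mixing",
            "attacker",
            "victim",
            "standoff",
            "duration_s",
        ],
    )
    if len(table):
        hours = table["hours_since_mixing"].astype(float).apply(int)
        counts = hours.value_counts().sort_index()
        hourly = pd.DataFrame(
            {"pen_id": pen_id, "hour_since_mixing": counts.index, "n_fights": counts.values}
        )
    else:
        hourly = pd.DataFrame(columns=["pen_id", "hour_since_mixing", "n_fights"])
    return TimelineResult(pen_id, table, hourly)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis and write all artifacts under ``config.out_dir``.

    Artifacts: per-pen networks (edge CSV + GraphML) under ``networks/``,
    ``centrality.csv``, ``summary_levels.csv`` (median/range with
    significance letters), ``correlations_within.csv``,
    ``correlations_cross.csv``, ``timeline.csv`` + ``timeline_hourly.csv``
    and ``run_log.yaml``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    trajectories: list[AnimalTrajectory]
    if config.simulate is not None:
        rosters, trajectories, events = generate_study(config.simulate)
        write_events(events, out / "simulated_events.csv")
        write_roster(rosters, out / "simulated_roster.csv")
        write_trajectories(trajectories, out / "simulated_trajectories.csv")
    else:
        events = read_events(config.events_path)
        rosters = read_roster(config.roster_path)
        checksums["events"] = _sha256(Path(config.events_path))
        checksums["roster"] = _sha256(Path(config.roster_path))
        if config.trajectories_path is not None:
            trajectories = read_trajectories(config.trajectories_path)
            checksums["trajectories"] = _sha256(Path(config.trajectories_path))
        else:
            trajectories = []

    events = filter_events(events, config.windows, config.min_duration)

    nets_dir = out / "networks"
    nets_dir.mkdir(exist_ok=True)
    by_pen: dict[tuple[str, str], list[FightEvent]] = {}
    for ev in events:
        by_pen.setdefault((ev.pen_id, ev.age_level.value), []).append(ev)
    nets: list[PenNetwork] = []
    for roster in rosters:
        net = build_network(by_pen.get((roster.pen_id, roster.age_level.value), []), roster)
        nets.append(net)
        write_edge_csv(net, nets_dir / f"{net.pen_id}.csv")
        write_graphml(net, nets_dir / f"{net.pen_id}.graphml")

    records = centrality_table(
        nets,
        scaling=config.closeness_scaling,
        standardize_degree=config.standardize_degree,
    )
    records.to_csv(out / "centrality.csv", index=False)

    if events:
        summary, _ = level_comparison_table(
            records,
            alpha=config.letters_alpha,
            pen_median=config.pen_median,
            bonferroni=config.bonferroni,
        )
        levels = [lv for lv in ("weaned", "growing", "gilt") if lv in set(records["age_level"])]
        within = [r for lv in levels for r in within_level_correlations(records, lv)]
        cross = cross_level_correlations(records, trajectories) if trajectories else []
    else:
        logger.warning("no events after filtering: rank statistics skipped")
        summary = pd.DataFrame(
            columns=[
                "measure", "age_level", "n", "median", "min", "max",
                "letter", "H", "df", "p_value", "p_formatted",
            ]
        )
        within, cross = [], []
    summary.to_csv(out / "summary_levels.csv", index=False)
    correlations_to_frame(within).to_csv(out / "correlations_within.csv", index=False)
    correlations_to_frame(cross).to_csv(out / "correlations_cross.csv", index=False)

    timelines = [timeline_export(events, roster.pen_id, config.windows) for roster in rosters]
    pd.concat([t.table for t in timelines], ignore_index=True).to_csv(
        out / "timeline.csv", index=False
    )
    pd.concat([t.hourly for t in timelines], ignore_index=True).to_csv(
        out / "timeline_hourly.csv", index=False
    )

    log = {
        "agonet_version": __version__,
        "seed": None if config.simulate is None else config.simulate.seed,
        "n_events_analyzed": len(events),
        "n_pens": len(rosters),
        "input_checksums": checksums,
        "settings": {
            "window_rule": "start-inclusive, end-exclusive",
            "observation_windows": [
                {"day": w.day, "start": w.start.isoformat("minutes"), "end": w.end.isoformat("minutes")}
                for w in config.windows
            ],
            "min_duration_s": config.min_duration,
            "standoff_rule": "half weight to each direction",
            "undirected_projection": "summed directional weights",
            "weighted_distance": config.weighted_distance,
            "closeness_scaling": config.closeness_scaling,
            "betweenness_normalization": "(n-1)(n-2)",
            "degree_standardized": config.standardize_degree,
            "letters_alpha": config.letters_alpha,
            "letters_bonferroni": config.bonferroni,
            "pooling": "pen medians" if config.pen_median else "animals pooled across pens",
            "measures": MEASURE_COLUMNS,
        },
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False), encoding="utf-8")
    return out
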