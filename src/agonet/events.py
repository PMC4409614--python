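"""Fight-event logs, pen rosters and animal trajectories.

Agonistic interactions between group-housed pigs are recorded as one event
per fight: the pen, the age level at which the pen was mixed, the two
animals involved, the start time, the duration and whether the fight was a
stand-off (initiator and receiver could not be identified).  Times are
expressed relative to the mixing day: ``D:HH:MM:SS`` where ``D`` is the
1-based day since mixing.  Observation is restricted to two days after
mixing, excluding the night (day 1 12:00-18:00, day 2 07:00-18:00).

Rosters list the full membership of every pen so that animals that never
fought appear as isolated nodes downstream.  Trajectories link the same
individual across successive mixing events (age levels).
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class AgeLevel(str, enum.Enum):
    """The three successive mixing situations followed in the study design."""

    WEANED = "weaned"
    GROWING = "growing"
    GILT = "gilt"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Chronological order of the age levels (used for consecutive-level pairing).
AGE_ORDER: tuple[AgeLevel, ...] = (AgeLevel.WEANED, AgeLevel.GROWING, AgeLevel.GILT)


class SchemaError(ValueError):
    """A CSV file does not carry the documented column set."""


class ValidationError(ValueError):
    """A record violates an invariant (self-fight, bad timestamp, ...)."""


_TIME_RE = re.compile(r"^(\d+):(\d{1,2}):(\d{2}):(\d{2})$")


@dataclass(frozen=True, order=True)
class StudyTime:
    """A second-resolution timestamp relative to the mixing day.

    ``day`` is 1-based (day 1 = day of mixing); ``second`` is the second of
    that day (0..86399).  Serialized as ``D:HH:MM:SS``.
    """

    day: int
    second: int

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValidationError(f"day must be >= 1, got {self.day}")
        if not 0 <= self.second < 86400:
            raise ValidationError(f"second of day out of range: {self.second}")

    @classmethod
    def parse(cls, text: str) -> "StudyTime":
        m = _TIME_RE.match(text.strip())
        if m is None:
            raise ValidationError(f"unparseable timestamp {text!r} (expected D:HH:MM:SS)")
        day, hh, mm, ss = (int(g) for g in m.groups())
        if hh > 23 or mm > 59 or ss > 59:
            raise ValidationError(f"unparseable timestamp {text!r} (clock out of range)")
        return cls(day, hh * 3600 + mm * 60 + ss)

    @classmethod
    def from_clock(cls, day: int, clock: time) -> "StudyTime":
        return cls(day, clock.hour * 3600 + clock.minute * 60 + clock.second)

    def total_seconds(self) -> int:
        """Seconds since midnight of the mixing day."""
        return (self.day - 1) * 86400 + self.second

    def __str__(self) -> str:
        hh, rem = divmod(self.second, 3600)
        mm, ss = divmod(rem, 60)
        return f"{self.day}:{hh:02d}:{mm:02d}:{ss:02d}"


@dataclass(frozen=True)
class ObservationWindow:
    """One continuous observation period within a single day.

    Membership is half-open: an event starting exactly at ``start`` is
    inside the window, one starting exactly at ``end`` is not.
    """

    day: int
    start: time
    end: time

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValidationError(f"window day must be >= 1, got {self.day}")
        if not self.start < self.end:
            raise ValidationError(f"window start {self.start} must precede end {self.end}")

    @property
    def start_second(self) -> int:
        return self.start.hour * 3600 + self.start.minute * 60 + self.start.second

    @property
    def end_second(self) -> int:
        return self.end.hour * 3600 + self.end.minute * 60 + self.end.second

    def contains(self, t: StudyTime) -> bool:
        return t.day == self.day and self.start_second <= t.second < self.end_second


#: The study's two-day, 17-hour observation scheme.
DEFAULT_WINDOWS: tuple[ObservationWindow, ...] = (
    ObservationWindow(1, time(12, 0), time(18, 0)),
    ObservationWindow(2, time(7, 0), time(18, 0)),
)


@dataclass(frozen=True)
class FightEvent:
    """One recorded agonistic interaction between two identified animals.

    When ``standoff`` is False, ``animal_a`` is the initiator and
    ``animal_b`` the receiver.  When True the fight had no identifiable
    initiator and (a, b) is an unordered pair of participants.
    """

    pen_id: str
    age_level: AgeLevel
    animal_a: str
    animal_b: str
    start_time: StudyTime
    duration: int
    standoff: bool = False

    def __post_init__(self) -> None:
        if self.animal_a == self.animal_b:
            raise ValidationError(
                f"self-fight: animal_a == animal_b == {self.animal_a!r}"
            )
        if self.duration < 0:
            raise ValidationError(f"duration must be non-negative, got {self.duration}")

    @property
    def participants(self) -> frozenset[str]:
        return frozenset((self.animal_a, self.animal_b))


@dataclass(frozen=True)
class PenRoster:
    """Full membership of one pen at one age level."""

    pen_id: str
    age_level: AgeLevel
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"roster for pen {self.pen_id!r} is empty")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class AnimalTrajectory:
    """Pen placements of one individual across the age levels it was tracked in."""

    animal_id: str
    placements: Mapping[AgeLevel, str] = field(default_factory=dict)

    def pen_at(self, level: AgeLevel) -> str | None:
        return self.placements.get(level)


EVENT_COLUMNS = (
    "pen_id",
    "age_level",
    "animal_a",
    "animal_b",
    "start_time",
    "duration_s",
    "standoff",
)
ROSTER_COLUMNS = ("pen_id", "age_level", "animal_id")
TRAJECTORY_COLUMNS = ("animal_id", "weaned_pen", "growing_pen", "gilt_pen")

_LEVEL_TO_TRAJ_COLUMN = {
    AgeLevel.WEANED: "weaned_pen",
    AgeLevel.GROWING: "growing_pen",
    AgeLevel.GILT: "gilt_pen",
}


def _check_header(fieldnames: Sequence[str] | None, required: Sequence[str], path: Path) -> None:
    present = set(fieldnames or ())
    for col in required:
        if col not in present:
            raise SchemaError(f"{path}: missing column {col!r}")


def _parse_level(text: str, where: str) -> AgeLevel:
    try:
        return AgeLevel(text.strip())
    except ValueError:
        raise ValidationError(
            f"{where}: unknown age level {text!r} (expected one of "
            f"{[l.value for l in AgeLevel]})"
        ) from None


def read_events(path: str | Path) -> list[FightEvent]:
    """Read a fight-event log CSV, preserving file order.

    Raises :class:`SchemaError` for a missing column and
    :class:`ValidationError` (with the row number) for bad rows.
    """
    path = Path(path)
    events: list[FightEvent] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, EVENT_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            try:
                standoff_raw = row["standoff"].strip()
                if standoff_raw not in ("0", "1"):
                    raise ValidationError(f"standoff must be 0 or 1, got {standoff_raw!r}")
                events.append(
                    FightEvent(
                        pen_id=row["pen_id"].strip(),
                        age_level=_parse_level(row["age_level"], where),
                        animal_a=row["animal_a"].strip(),
                        animal_b=row["animal_b"].strip(),
                        start_time=StudyTime.parse(row["start_time"]),
                        duration=int(row["duration_s"]),
                        standoff=standoff_raw == "1",
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{where}: {exc}") from None
            except (KeyError, TypeError) as exc:  # row shorter than header
                raise ValidationError(f"{where}: malformed row ({exc})") from None
    return events


def write_events(events: Iterable[FightEvent], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for ev in events:
            writer.writerow(
                [
                    ev.pen_id,
                    ev.age_level.value,
                    ev.animal_a,
                    ev.animal_b,
                    str(ev.start_time),
                    ev.duration,
                    int(ev.standoff),
                ]
            )


def read_roster(path: str | Path) -> list[PenRoster]:
    """Read pen rosters, grouped by (pen_id, age_level), in first-seen order.

    An animal listed in two different pens at the same age level is a
    validation error.
    """
    path = Path(path)
    pens: dict[tuple[str, AgeLevel], list[str]] = {}
    seen: dict[tuple[str, AgeLevel], str] = {}  # (animal, level) -> pen
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, ROSTER_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            pen_id = row["pen_id"].strip()
            level = _parse_level(row["age_level"], where)
            animal = row["animal_id"].strip()
            key = (animal, level)
            if key in seen and seen[key] != pen_id:
                raise ValidationError(
                    f"{where}: animal {animal!r} placed in both pen "
                    f"{seen[key]!r} and {pen_id!r} at level {level.value}"
                )
            seen[key] = pen_id
            pens.setdefault((pen_id, level), []).append(animal)
    return [
        PenRoster(pen_id, level, frozenset(members))
        for (pen_id, level), members in pens.items()
    ]


def write_roster(rosters: Iterable[PenRoster], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROSTER_COLUMNS)
        for roster in rosters:
            for animal in sorted(roster.members):
                writer.writerow([roster.pen_id, roster.age_level.value, animal])


def read_trajectories(path: str | Path) -> list[AnimalTrajectory]:
    """Read the animal-trajectory table (one row per animal, empty cell = absent)."""
    path = Path(path)
    out: list[AnimalTrajectory] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, TRAJECTORY_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            animal = row["animal_id"].strip()
            if animal in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate animal {animal!r}")
            seen.add(animal)
            placements = {
                level: row[col].strip()
                for level, col in _LEVEL_TO_TRAJ_COLUMN.items()
                if row[col] is not None and row[col].strip()
            }
            out.append(AnimalTrajectory(animal, placements))
    return out


def write_trajectories(trajectories: Iterable[AnimalTrajectory], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRAJECTORY_COLUMNS)
        for traj in trajectories:
            writer.writerow(
                [traj.animal_id]
                + [traj.placements.get(level, "") for level in AGE_ORDER]
            )


def filter_events(
    events: Iterable[FightEvent],
    windows: Sequence[ObservationWindow] = DEFAULT_WINDOWS,
    min_duration: int = 1,
) -> list[FightEvent]:
    """Keep events starting inside some observation window with duration >= min_duration.

    Window membership is start-inclusive / end-exclusive.  Event order is
    preserved; the operation is idempotent.
    """
    return [
        ev
        for ev in events
        if ev.duration >= min_duration and any(w.contains(ev.start_time) for w in windows)
    ]
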