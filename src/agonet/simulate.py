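"""Synthetic agonistic-interaction studies.

The generator emulates the structure of a three-stage pig study: the same
population is mixed into new pens at three age levels (weaned pigs in small
flatdeck groups, growing pigs and gilts in larger groups), and fights are
recorded for a 17-hour window over the two days after each mixing (day 1
12:00-18:00, day 2 07:00-18:00).

Data-generating model, per pen:

* every animal carries a latent log-aggressiveness trait ``z ~ N(0, sd)``;
  at the next age level the trait is resampled jointly so that consecutive
  levels have a configurable correlation (same marginal);
* the number of fights an animal initiates is Poisson with mean
  ``mean_fights * exp(z - sd^2/2)`` (a log-normal multiplier with mean 1,
  giving the heavy right tail seen in real fight counts);
* victims are drawn uniformly among pen mates;
* each fight is a stand-off (no identifiable initiator) with a fixed
  probability;
* fight start times fall inside the observation windows, thinned as
  ``exp(-decay * t)`` in hours since mixing — zero decay for weaned pigs
  (fighting stays spread over both days), positive decay for the older
  levels (most fighting in the first hours after mixing).

Everything is reproducible from a single seed: one shared random stream is
consumed in a fixed level/pen order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import time
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .events import (
    AGE_ORDER,
    AgeLevel,
    AnimalTrajectory,
    DEFAULT_WINDOWS,
    FightEvent,
    ObservationWindow,
    PenRoster,
    StudyTime,
)


class ConfigError(ValueError):
    """The synthetic-study configuration is invalid or infeasible."""


def _default_groups() -> dict[AgeLevel, int]:
    return {AgeLevel.WEANED: 65, AgeLevel.GROWING: 24, AgeLevel.GILT: 12}


def _default_sizes() -> dict[AgeLevel, tuple[int, int]]:
    return {AgeLevel.WEANED: (6, 11), AgeLevel.GROWING: (20, 25), AgeLevel.GILT: (18, 29)}


def _default_means() -> dict[AgeLevel, float]:
    # weaned pens fight roughly twice as intensely per animal as the older levels
    return {AgeLevel.WEANED: 6.0, AgeLevel.GROWING: 2.5, AgeLevel.GILT: 2.5}


def _default_decay() -> dict[AgeLevel, float]:
    # per-hour thinning rate; older animals concentrate fighting after mixing
    return {AgeLevel.WEANED: 0.0, AgeLevel.GROWING: 0.1, AgeLevel.GILT: 0.1}


@dataclass
class SyntheticConfig:
    """Full parameterization of the study emulator."""

    seed: int = 0
    groups_per_level: dict[AgeLevel, int] = field(default_factory=_default_groups)
    group_size_ranges: dict[AgeLevel, tuple[int, int]] = field(default_factory=_default_sizes)
    mean_fights_per_animal: dict[AgeLevel, float] = field(default_factory=_default_means)
    temporal_decay_rate: dict[AgeLevel, float] = field(default_factory=_default_decay)
    trait_sd: float = 0.8
    cross_level_trait_correlation: float = 0.3
    standoff_probability: float = 0.1
    observation_windows: tuple[ObservationWindow, ...] = DEFAULT_WINDOWS

    def validate(self) -> None:
        for level in AGE_ORDER:
            lo, hi = self.group_size_ranges[level]
            if not (2 <= lo <= hi):
                raise ConfigError(f"invalid size range {lo}..{hi} for {level.value}")
            if self.groups_per_level[level] < 0:
                raise ConfigError(f"negative group count for {level.value}")
            if self.mean_fights_per_animal[level] < 0:
                raise ConfigError(f"negative mean fights for {level.value}")
            if self.temporal_decay_rate[level] < 0:
                raise ConfigError(f"negative decay rate for {level.value}")
        if self.trait_sd < 0:
            raise ConfigError("trait_sd must be non-negative")
        if not -1.0 <= self.cross_level_trait_correlation <= 1.0:
            raise ConfigError("cross_level_trait_correlation must lie in [-1, 1]")
        if not 0.0 <= self.standoff_probability <= 1.0:
            raise ConfigError("standoff_probability must lie in [0, 1]")
        if not self.observation_windows:
            raise ConfigError("at least one observation window is required")

    # -- YAML round trip --------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs: dict = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        for name in ("trait_sd", "cross_level_trait_correlation", "standoff_probability"):
            if name in raw:
                kwargs[name] = float(raw[name])
        for name, cast in (
            ("groups_per_level", int),
            ("mean_fights_per_animal", float),
            ("temporal_decay_rate", float),
        ):
            if name in raw:
                kwargs[name] = {AgeLevel(k): cast(v) for k, v in raw[name].items()}
        if "group_size_ranges" in raw:
            kwargs["group_size_ranges"] = {
                AgeLevel(k): (int(v[0]), int(v[1])) for k, v in raw["group_size_ranges"].items()
            }
        if "observation_windows" in raw:
            kwargs["observation_windows"] = tuple(
                ObservationWindow(
                    int(w["day"]), time.fromisoformat(str(w["start"])), time.fromisoformat(str(w["end"]))
                )
                for w in raw["observation_windows"]
            )
        config = cls(**kwargs)
        config.validate()
        return config

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "groups_per_level": {k.value: v for k, v in self.groups_per_level.items()},
            "group_size_ranges": {k.value: list(v) for k, v in self.group_size_ranges.items()},
            "mean_fights_per_animal": {k.value: v for k, v in self.mean_fights_per_animal.items()},
            "temporal_decay_rate": {k.value: v for k, v in self.temporal_decay_rate.items()},
            "trait_sd": self.trait_sd,
            "cross_level_trait_correlation": self.cross_level_trait_correlation,
            "standoff_probability": self.standoff_probability,
            "observation_windows": [
                {"day": w.day, "start": w.start.isoformat("minutes"), "end": w.end.isoformat("minutes")}
                for w in self.observation_windows
            ],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")

    def scaled(self, **overrides) -> "SyntheticConfig":
        """Copy with field overrides (convenience for reduced designs)."""
        return replace(self, **overrides)


# -- fight-time sampling ---------------------------------------------------

def _window_intervals(
    windows: Sequence[ObservationWindow],
) -> list[tuple[ObservationWindow, float, float]]:
    """Windows as [start, end) intervals in hours since mixing.

    Mixing is anchored at the start of the earliest window.
    """
    ordered = sorted(windows, key=lambda w: (w.day, w.start_second))
    mix_h = (ordered[0].day - 1) * 24.0 + ordered[0].start_second / 3600.0
    out = []
    for w in ordered:
        a = (w.day - 1) * 24.0 + w.start_second / 3600.0 - mix_h
        b = (w.day - 1) * 24.0 + w.end_second / 3600.0 - mix_h
        out.append((w, a, b))
    return out


def hours_since_mixing(t: StudyTime, windows: Sequence[ObservationWindow] = DEFAULT_WINDOWS) -> float:
    """Elapsed hours between mixing (start of the first window) and ``t``."""
    ordered = sorted(windows, key=lambda w: (w.day, w.start_second))
    mix_h = (ordered[0].day - 1) * 24.0 + ordered[0].start_second / 3600.0
    return t.total_seconds() / 3600.0 - mix_h


def _sample_fight_times(
    rng: np.random.Generator,
    k: int,
    decay: float,
    intervals: Sequence[tuple[ObservationWindow, float, float]],
) -> list[StudyTime]:
    """Draw k fight start times from the exponentially thinned window density."""
    if k == 0:
        return []
    if decay > 0:
        masses = np.array([(np.exp(-decay * a) - np.exp(-decay * b)) / decay for _, a, b in intervals])
    else:
        masses = np.array([b - a for _, a, b in intervals])
    cum = np.cumsum(masses / masses.sum())
    which = np.searchsorted(cum, rng.random(k), side="right")
    u = rng.random(k)
    times: list[StudyTime] = []
    for idx, ui in zip(which, u):
        w, a, b = intervals[idx]
        if decay > 0:
            ea, eb = np.exp(-decay * a), np.exp(-decay * b)
            t = -np.log(ea - ui * (ea - eb)) / decay
        else:
            t = a + ui * (b - a)
        sec = w.start_second + int((t - a) * 3600.0)
        sec = min(sec, w.end_second - 1)  # keep strictly inside the half-open window
        times.append(StudyTime(w.day, sec))
    return times


# -- generators ------------------------------------------------------------

def generate_pen(
    size: int,
    mean_fights: float,
    decay: float,
    standoff_p: float,
    rng: np.random.Generator,
    *,
    pen_id: str = "P1",
    age_level: AgeLevel = AgeLevel.WEANED,
    windows: Sequence[ObservationWindow] = DEFAULT_WINDOWS,
    animal_ids: Sequence[str] | None = None,
    trait_multipliers: Sequence[float] | None = None,
    trait_sd: float = 0.0,
) -> list[FightEvent]:
    """Generate one pen's chronologically sorted fight log.

    ``trait_multipliers`` scale each animal's expected initiated-fight
    count; when absent they are drawn log-normally with dispersion
    ``trait_sd`` (mean 1), or set to 1 if ``trait_sd`` is 0.
    """
    if size < 2:
        raise ConfigError(f"pen size must be >= 2, got {size}")
    if animal_ids is None:
        animal_ids = [f"{pen_id}_{i + 1:02d}" for i in range(size)]
    if len(set(animal_ids)) != size:
        raise ConfigError("animal_ids must be unique and match size")
    if trait_multipliers is None:
        if trait_sd > 0:
            z = rng.normal(0.0, trait_sd, size)
            trait_multipliers = np.exp(z - trait_sd**2 / 2.0)
        else:
            trait_multipliers = np.ones(size)
    mult = np.asarray(trait_multipliers, dtype=float)
    counts = rng.poisson(mean_fights * mult)
    total = int(counts.sum())
    if total == 0:
        return []
    initiators = np.repeat(np.arange(size), counts)
    victims = rng.integers(0, size - 1, total)
    victims[victims >= initiators] += 1
    times = _sample_fight_times(rng, total, decay, _window_intervals(windows))
    standoffs = rng.random(total) < standoff_p
    durations = np.maximum(1, np.round(np.exp(rng.normal(2.5, 0.8, total)))).astype(int)
    events = [
        FightEvent(
            pen_id=pen_id,
            age_level=age_level,
            animal_a=animal_ids[i],
            animal_b=animal_ids[j],
            start_time=t,
            duration=int(d),
            standoff=bool(s),
        )
        for i, j, t, s, d in zip(initiators, victims, times, standoffs, durations)
    ]
    events.sort(key=lambda e: (e.start_time, e.animal_a, e.animal_b, e.duration))
    return events


def _fit_sizes_to_pool(sizes: np.ndarray, pool: int, lo: int, level: AgeLevel) -> np.ndarray:
    """Shrink the largest groups (down to the range minimum) until they fit the pool."""
    sizes = sizes.copy()
    if sizes.size * lo > pool:
        raise ConfigError(
            f"{level.value}: {sizes.size} groups of at least {lo} animals "
            f"exceed the {pool} animals available from the previous level"
        )
    while sizes.sum() > pool:
        i = int(np.argmax(sizes))
        if sizes[i] <= lo:
            raise ConfigError(f"{level.value}: cannot fit groups into animal pool")
        sizes[i] -= 1
    return sizes


def generate_study(
    config: SyntheticConfig,
) -> tuple[list[PenRoster], list[AnimalTrajectory], list[FightEvent]]:
    """Generate a full three-level study: rosters, trajectories and events.

    The weaned-level pens define the animal population; at each subsequent
    level a random subset is re-mixed into new pens, and each animal's
    latent trait is resampled with the configured consecutive-level
    correlation.  Output order is deterministic (levels in age order, pens
    in index order, events chronological within a pen).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sd = config.trait_sd
    rho = config.cross_level_trait_correlation

    rosters: list[PenRoster] = []
    events: list[FightEvent] = []
    placements: dict[str, dict[AgeLevel, str]] = {}

    pool_ids: list[str] = []
    pool_z: np.ndarray | None = None
    for level in AGE_ORDER:
        n_groups = config.groups_per_level[level]
        if n_groups == 0:
            continue
        lo, hi = config.group_size_ranges[level]
        sizes = rng.integers(lo, hi + 1, n_groups)
        if pool_z is None:  # first level creates the population
            total = int(sizes.sum())
            ids = [f"A{i + 1:04d}" for i in range(total)]
            z = rng.normal(0.0, sd, total)
        else:
            sizes = _fit_sizes_to_pool(sizes, len(pool_ids), lo, level)
            total = int(sizes.sum())
            chosen = rng.permutation(len(pool_ids))[:total]
            ids = [pool_ids[i] for i in chosen]
            eps = rng.normal(0.0, sd, total)
            z = rho * pool_z[chosen] + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
        mult = np.exp(z - sd**2 / 2.0) if sd > 0 else np.ones(total)
        offset = 0
        for g, size in enumerate(sizes):
            size = int(size)
            pen_id = f"{level.value}-{g + 1:02d}"
            pen_ids = ids[offset : offset + size]
            pen_mult = mult[offset : offset + size]
            offset += size
            rosters.append(PenRoster(pen_id, level, frozenset(pen_ids)))
            for animal in pen_ids:
                placements.setdefault(animal, {})[level] = pen_id
            events.extend(
                generate_pen(
                    size,
                    config.mean_fights_per_animal[level],
                    config.temporal_decay_rate[level],
                    config.standoff_probability,
                    rng,
                    pen_id=pen_id,
                    age_level=level,
                    windows=config.observation_windows,
                    animal_ids=pen_ids,
                    trait_multipliers=pen_mult,
                )
            )
        pool_ids = ids
        pool_z = z

    trajectories = [
        AnimalTrajectory(animal, dict(placements[animal])) for animal in sorted(placements)
    ]
    return rosters, trajectories, events
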