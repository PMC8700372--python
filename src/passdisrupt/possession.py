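"""Possession segmentation, pass extraction and the deliberate-attack filter.

A possession opens at the first controlled action of a team and closes when
the opponent gains control or play stops (ball out of bounds, free kick,
corner, goal kick, goal, foul).  Stoppage events close possessions but belong
to neither side.  Deliberate attacks are possessions lasting strictly longer
than 5 s with at least 3 completed passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, OrderingError
from .tracking import TrackingSeries

log = logging.getLogger(__name__)

#: Event types that represent a team controlling the ball.
CONTROLLED_TYPES = frozenset({"pass", "reception", "interception", "shot"})
#: Event types that stop play and close the current possession.
STOPPAGE_TYPES = frozenset({"out_of_bounds", "free_kick", "corner", "goal_kick", "goal", "foul"})


@dataclass
class PassRecord:
    """A single pass: release and reception endpoints in match coordinates."""

    passer: str
    team: str
    t_pass: float
    release: np.ndarray
    receiver: str | None = None
    t_reception: float | None = None
    reception: np.ndarray | None = None
    completed: bool = False

    def __post_init__(self):
        if self.completed:
            if self.t_reception is None or self.t_reception <= self.t_pass:
                raise ConsistencyError(
                    f"completed pass at t={self.t_pass} requires t_reception > t_pass"
                )


@dataclass
class Possession:
    """One interval of ball control by a single team."""

    team: str
    start: float
    end: float
    events: pd.DataFrame
    passes: list[PassRecord] = field(default_factory=list)
    termination: str = "stoppage"  # or "opponent_gain"

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def completed_passes(self) -> list[PassRecord]:
        return [p for p in self.passes if p.completed]


@dataclass
class Attack:
    """A possession that passed the deliberate-attack filter."""

    attack_id: str
    possession: Possession
    success: bool | None = None

    @property
    def team(self) -> str:
        return self.possession.team

    @property
    def duration(self) -> float:
        return self.possession.duration

    @property
    def n_passes(self) -> int:
        return len(self.possession.completed_passes)


def segment_possessions(events: pd.DataFrame) -> list[Possession]:
    """Split a time-ordered event stream into disjoint possessions."""
    times = events["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(times) < 0):
        raise OrderingError("events must be time-ordered")

    possessions: list[Possession] = []
    current_team: str | None = None
    current_rows: list[int] = []
    start: float | None = None

    def close(end: float, reason: str) -> None:
        nonlocal current_team, current_rows, start
        if current_team is None:
            return
        if end <= start:
            # degenerate interval (e.g. a lone gain of control at stream end)
            current_team, current_rows, start = None, [], None
            return
        poss = Possession(
            team=current_team,
            start=float(start),
            end=float(end),
            events=events.iloc[current_rows].reset_index(drop=True),
            termination=reason,
        )
        poss.passes = extract_passes(poss)
        possessions.append(poss)
        current_team, current_rows, start = None, [], None

    for i, row in enumerate(events.itertuples(index=False)):
        if row.type in STOPPAGE_TYPES:
            close(row.time_s, "stoppage")
        elif row.type in CONTROLLED_TYPES:
            if current_team is None:
                current_team, start = row.team, row.time_s
                current_rows = [i]
            elif row.team != current_team:
                close(row.time_s, "opponent_gain")
                current_team, start = row.team, row.time_s
                current_rows = [i]
            else:
                current_rows.append(i)
    if current_team is not None:
        close(float(times[-1]), "stoppage")
    return possessions


def extract_passes(possession: Possession) -> list[PassRecord]:
    """Pair pass events with the next same-team reception inside the possession.

    A new pass before the previous one was received marks the previous pass
    incomplete; trailing unreceived passes are incomplete as well.  Receptions
    with no preceding pass are skipped with a warning.
    """
    records: list[PassRecord] = []
    pending: PassRecord | None = None
    for row in possession.events.itertuples(index=False):
        if row.type == "pass" and row.team == possession.team:
            if pending is not None:
                records.append(pending)  # superseded -> incomplete
            pending = PassRecord(
                passer=row.player_id,
                team=row.team,
                t_pass=float(row.time_s),
                release=np.array([row.x, row.y], dtype=float),
            )
        elif row.type == "reception" and row.team == possession.team:
            if pending is None:
                log.warning(
                    "reception at t=%.3f without a preceding pass; skipped", row.time_s
                )
                continue
            if row.time_s <= pending.t_pass:
                raise ConsistencyError(
                    f"reception at t={row.time_s} not after pass at t={pending.t_pass}"
                )
            pending.receiver = row.player_id
            pending.t_reception = float(row.time_s)
            pending.reception = np.array([row.x, row.y], dtype=float)
            pending.completed = True
            records.append(pending)
            pending = None
    if pending is not None:
        records.append(pending)
    return records


def filter_deliberate(
    possessions: list[Possession],
    min_duration: float = 5.0,
    min_passes: int = 3,
    id_prefix: str = "a",
) -> list[Attack]:
    """Keep possessions with duration strictly > ``min_duration`` seconds and
    at least ``min_passes`` completed passes."""
    attacks = []
    for poss in possessions:
        if poss.duration > min_duration and len(poss.completed_passes) >= min_passes:
            attacks.append(Attack(attack_id=f"{id_prefix}{len(attacks):04d}", possession=poss))
    return attacks


def last_k_passes(attack: Attack, k: int = 4) -> list[PassRecord]:
    """Last ``k`` completed passes, index 1 = final pass, 2 = penultimate
    ("hockey assist"), and so on.  Element ``i`` of the returned list is
    pass ``i+1``."""
    completed = attack.possession.completed_passes
    return list(reversed(completed[-k:]))


def attach_possession(series: TrackingSeries, possessions: list[Possession]) -> TrackingSeries:
    """Label every frame with the team in control at that time ("" if none)."""
    labels = np.array([""] * series.n_frames, dtype=object)
    for poss in possessions:
        mask = (series.times >= poss.start) & (series.times <= poss.end)
        labels[mask] = poss.team
    out = series.copy()
    out.possession = labels
    return out


def attacks_table(attacks: list[Attack]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "attack_id": [a.attack_id for a in attacks],
            "team": [a.team for a in attacks],
            "start_s": [a.possession.start for a in attacks],
            "end_s": [a.possession.end for a in attacks],
            "duration_s": [a.duration for a in attacks],
            "n_passes": [a.n_passes for a in attacks],
        }
    )
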