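"""Formation-line detection: cluster average player depth into DEF/MID/ATT.

Players are clustered by k-means (k = 3, 10 restarts, fixed seed) on the
longitudinal coordinate of their average position, computed in the team's
attack-normalised frame so the defensive line always has the smallest x.
The goalkeeper is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import DataGapError, DegenerateInputError, InsufficientDataError
from .tracking import BALL, TrackingSeries, normalize_attack_direction

LINE_LABELS = ("DEF", "MID", "ATT")


@dataclass
class LineAssignment:
    team: str
    phase: str  # "in_possession" | "out_of_possession"
    labels: dict[str, str]  # player id -> DEF/MID/ATT
    centers: np.ndarray  # (3,) longitudinal centres, ascending
    sizes: tuple[int, int, int]

    def __post_init__(self):
        if not (self.centers[0] < self.centers[1] < self.centers[2]):
            raise DegenerateInputError("line centres must be strictly ordered DEF < MID < ATT")
        if sum(self.sizes) != len(self.labels):
            raise DegenerateInputError("line sizes must sum to the number of assigned players")

    def players_in(self, line: str) -> list[str]:
        return [p for p, l in self.labels.items() if l == line]


def average_positions(
    series: TrackingSeries,
    team: str,
    half: int = 1,
    phase: str = "out_of_possession",
) -> dict[str, np.ndarray]:
    """Per-player mean attack-normalised position over first-half frames of
    the requested possession phase.  Requires a possession-labelled series."""
    if series.possession is None:
        raise DataGapError("series has no possession labels; run attach_possession first")
    normalized = normalize_attack_direction(series, team)
    halves = np.array([series.meta.half_of(t) for t in series.times])
    if phase == "in_possession":
        phase_mask = series.possession == team
    elif phase == "out_of_possession":
        opponent = series.meta.opponent(team)
        phase_mask = series.possession == opponent
    else:
        raise ValueError(f"unknown phase {phase!r}")
    mask = (halves == half) & phase_mask
    if not mask.any():
        raise InsufficientDataError(f"no half-{half} frames in phase {phase!r} for {team!r}")
    gk = series.meta.goalkeepers.get(team)
    out: dict[str, np.ndarray] = {}
    for j, (t, pid) in enumerate(series.entities):
        if t != team or pid == gk or t == BALL:
            continue
        out[pid] = normalized.xy[mask, j, :].mean(axis=0)
    return out


def cluster_lines(
    avg_positions: dict[str, np.ndarray],
    team: str = "",
    phase: str = "out_of_possession",
    k: int = 3,
    seed: int = 0,
) -> LineAssignment:
    """K-means (on depth only) assignment of players to three formation lines."""
    if len(avg_positions) < k:
        raise InsufficientDataError(f"need at least {k} outfield players, got {len(avg_positions)}")
    players = sorted(avg_positions)
    x = np.array([avg_positions[p][0] for p in players], dtype=float)
    if len(np.unique(np.round(x, 9))) < k:
        raise DegenerateInputError("fewer than 3 distinct depth values; cannot form 3 lines")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw_labels = km.fit_predict(x.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    rank = {int(c): i for i, c in enumerate(order)}
    labels = {p: LINE_LABELS[rank[int(l)]] for p, l in zip(players, raw_labels)}
    centers = np.sort(km.cluster_centers_.ravel())
    sizes = tuple(sum(1 for l in labels.values() if l == line) for line in LINE_LABELS)
    return LineAssignment(team=team, phase=phase, labels=labels, centers=centers, sizes=sizes)


def formation_label(assignment: LineAssignment) -> str:
    """Render line sizes as the familiar formation string, e.g. "4-4-2"."""
    return "-".join(str(s) for s in assignment.sizes)


def assignment_table(assignments: list[LineAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        center = dict(zip(LINE_LABELS, a.centers))
        for pid, line in sorted(a.labels.items()):
            rows.append((a.team, a.phase, pid, line, center[line]))
    return pd.DataFrame(rows, columns=["team", "phase", "player_id", "line", "center_x"])


def detect_lines(
    series: TrackingSeries,
    team: str,
    phase: str = "out_of_possession",
    half: int = 1,
    seed: int = 0,
) -> LineAssignment:
    """Convenience composition: average positions -> k-means line assignment."""
    avg = average_positions(series, team, half=half, phase=phase)
    return cluster_lines(avg, team=team, phase=phase, seed=seed)
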