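"""Data model, I/O and preprocessing for player/ball tracking and ball events.

Coordinate convention: origin at pitch centre, x along the pitch length,
y along the width, metres, time in seconds from kickoff.  A team's
*attacking direction* is the sign of x toward the opponent goal; after
:func:`normalize_attack_direction` the attacking team always plays toward
``(+pitch_length/2, 0)``.

Tracking files are delimited text with header ``frame,time_s,team,player_id,x,y``
where the ball uses the reserved team/player label ``ball``.  Event files use
``time_s,type,team,player_id,x,y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    LookupError_,
    OrderingError,
    TrackingFormatError,
)

BALL = "ball"

#: Closed vocabulary of ball-event types.
EVENT_TYPES = frozenset(
    {
        "pass",
        "reception",
        "interception",
        "out_of_bounds",
        "free_kick",
        "corner",
        "goal_kick",
        "goal",
        "foul",
        "shot",
    }
)

TRACKING_COLUMNS = ["frame", "time_s", "team", "player_id", "x", "y"]
EVENT_COLUMNS = ["time_s", "type", "team", "player_id", "x", "y"]


@dataclass(frozen=True)
class Position:
    """A point on the pitch in metres (x: long axis, y: short axis)."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def validate(self, meta: "MatchMeta", slack: float = 5.0) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise TrackingFormatError(f"non-finite position {self!r}")
        if abs(self.x) > meta.pitch_length / 2 + slack or abs(self.y) > meta.pitch_width / 2 + slack:
            raise TrackingFormatError(f"position {self!r} outside pitch bounds (+{slack} m slack)")


@dataclass(frozen=True)
class MatchMeta:
    """Static match metadata: pitch geometry, teams, attacking directions.

    ``attacking_direction`` maps ``(team, half)`` to +1 or -1: the sign of x
    toward the opponent goal.  Directions must be opposite within a half and
    flip between halves.  ``half_boundary_s`` is the kickoff time of the
    second half; ``None`` means a single continuous period.
    """

    pitch_length: float = 105.0
    pitch_width: float = 68.0
    teams: tuple[str, str] = ("home", "away")
    sampling_rate: float = 10.0
    attacking_direction: Mapping[tuple[str, int], int] = field(
        default_factory=lambda: {("home", 1): 1, ("away", 1): -1}
    )
    half_boundary_s: float | None = None
    goalkeepers: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.pitch_length > self.pitch_width > 0):
            raise ConfigurationError("require pitch_length > pitch_width > 0")
        if len(self.teams) != 2 or self.teams[0] == self.teams[1]:
            raise ConfigurationError("exactly two distinct team labels required")
        halves = {h for (_, h) in self.attacking_direction}
        for h in halves:
            a, b = (self.attacking_direction.get((t, h)) for t in self.teams)
            if a is not None and b is not None and a + b != 0:
                raise ConfigurationError(f"teams must attack opposite directions in half {h}")
        if 1 in halves and 2 in halves:
            for t in self.teams:
                d1, d2 = self.attacking_direction.get((t, 1)), self.attacking_direction.get((t, 2))
                if d1 is not None and d2 is not None and d1 == d2:
                    raise ConfigurationError(f"attacking direction of {t} must flip between halves")

    def half_of(self, time_s: float) -> int:
        if self.half_boundary_s is not None and time_s >= self.half_boundary_s:
            return 2
        return 1

    def direction(self, team: str, half: int = 1) -> int:
        try:
            return self.attacking_direction[(team, half)]
        except KeyError:
            raise LookupError_(f"no attacking direction for team {team!r} in half {half}")

    def opponent(self, team: str) -> str:
        if team == self.teams[0]:
            return self.teams[1]
        if team == self.teams[1]:
            return self.teams[0]
        raise LookupError_(f"unknown team {team!r}")

    def to_yaml(self, path) -> None:
        payload = {
            "pitch_length": self.pitch_length,
            "pitch_width": self.pitch_width,
            "teams": list(self.teams),
            "sampling_rate": self.sampling_rate,
            "attacking_direction": [
                {"team": t, "half": h, "sign": int(s)}
                for (t, h), s in sorted(self.attacking_direction.items())
            ],
            "half_boundary_s": self.half_boundary_s,
            "goalkeepers": dict(self.goalkeepers),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "MatchMeta":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        direction = {
            (d["team"], int(d["half"])): int(d["sign"])
            for d in payload["attacking_direction"]
        }
        return cls(
            pitch_length=float(payload["pitch_length"]),
            pitch_width=float(payload["pitch_width"]),
            teams=tuple(payload["teams"]),
            sampling_rate=float(payload["sampling_rate"]),
            attacking_direction=direction,
            half_boundary_s=payload.get("half_boundary_s"),
            goalkeepers=payload.get("goalkeepers") or {},
        )


@dataclass
class TrackingFrame:
    """One instant of play: player positions, ball position, possession label."""

    time: float
    positions: dict[tuple[str, str], np.ndarray]
    ball: np.ndarray
    possession: str | None = None


@dataclass
class TrackingSeries:
    """A time-indexed panel of positions for all tracked entities.

    ``xy`` has shape ``(n_frames, n_entities, 2)``; ``entities`` lists
    ``(team, player_id)`` pairs in column order, with ``(ball, ball)``
    among them.  ``possession`` optionally labels the team in control at
    each frame ("" where unknown).
    """

    times: np.ndarray
    entities: list[tuple[str, str]]
    xy: np.ndarray
    meta: MatchMeta
    possession: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        n = self.times.shape[0]
        if self.xy.shape != (n, len(self.entities), 2):
            raise TrackingFormatError(
                f"xy shape {self.xy.shape} inconsistent with {n} frames x {len(self.entities)} entities"
            )
        if np.any(self.times < 0):
            raise OrderingError("negative timestamps")
        if n > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise OrderingError("timestamps must be strictly increasing")
            if np.ptp(dt) > 1e-6:
                raise OrderingError("inter-frame spacing must be constant (tolerance 1e-6 s)")
        for team in self.meta.teams:
            n_players = sum(1 for (t, _) in self.entities if t == team)
            if n_players > 11:
                raise TrackingFormatError(f"team {team!r} has {n_players} players (> 11)")

    # -- indexing helpers -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(self.times.shape[0])

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            return 1.0 / self.meta.sampling_rate
        return float(self.times[1] - self.times[0])

    def entity_index(self, team: str, player_id: str) -> int:
        try:
            return self.entities.index((team, player_id))
        except ValueError:
            raise LookupError_(f"entity ({team!r}, {player_id!r}) not tracked")

    def team_indices(self, team: str) -> list[int]:
        return [i for i, (t, _) in enumerate(self.entities) if t == team]

    def team_players(self, team: str) -> list[str]:
        return [p for (t, p) in self.entities if t == team]

    @property
    def ball_index(self) -> int:
        return self.entity_index(BALL, BALL)

    def ball_xy(self) -> np.ndarray:
        return self.xy[:, self.ball_index, :]

    def frame_index_at(self, time_s: float, tol: float | None = None) -> int:
        """Nearest frame index to ``time_s`` within ``tol`` (default dt/2)."""
        if tol is None:
            tol = self.dt / 2
        i = int(np.clip(np.searchsorted(self.times, time_s), 0, self.n_frames - 1))
        if i > 0 and abs(self.times[i - 1] - time_s) <= abs(self.times[i] - time_s):
            i -= 1
        if abs(self.times[i] - time_s) > tol + 1e-12:
            raise DataGapErrorFactory(time_s, self.times[i])
        return i

    def frame(self, i: int) -> TrackingFrame:
        positions = {
            ent: self.xy[i, j].copy()
            for j, ent in enumerate(self.entities)
            if ent[0] != BALL
        }
        poss = None
        if self.possession is not None:
            label = str(self.possession[i])
            poss = label if label else None
        return TrackingFrame(
            time=float(self.times[i]),
            positions=positions,
            ball=self.xy[i, self.ball_index].copy(),
            possession=poss,
        )

    def copy(self) -> "TrackingSeries":
        return TrackingSeries(
            times=self.times.copy(),
            entities=list(self.entities),
            xy=self.xy.copy(),
            meta=self.meta,
            possession=None if self.possession is None else self.possession.copy(),
        )


def DataGapErrorFactory(requested: float, nearest: float):
    from .errors import DataGapError

    return DataGapError(f"no frame within tolerance of t={requested:.3f} s (nearest {nearest:.3f} s)")


# ---------------------------------------------------------------------------
# I/O


def read_tracking(source, meta: MatchMeta) -> TrackingSeries:
    """Read a long-form tracking file into a :class:`TrackingSeries`.

    Each frame must contain one ``ball`` row and the same set of player rows;
    team labels must be one of ``meta.teams`` or ``ball``.
    """
    raw = pd.read_csv(source, dtype=str)
    missing = [c for c in TRACKING_COLUMNS if c not in raw.columns]
    if missing:
        raise TrackingFormatError(f"tracking file missing columns {missing}")
    for col in ("frame", "time_s", "x", "y"):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise TrackingFormatError(f"unparseable {col!r} value at line {line}")
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise TrackingFormatError(f"missing {col!r} value at line {line}")
        raw[col] = converted
    valid_teams = set(meta.teams) | {BALL}
    bad_team = ~raw["team"].isin(valid_teams)
    if bad_team.any():
        raise TrackingFormatError(f"unknown team label {raw['team'][bad_team].iloc[0]!r}")

    frame_ids = raw["frame"].unique()
    times = raw.groupby("frame", sort=False)["time_s"].first().to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise OrderingError("frame times are not strictly increasing")

    raw = raw.assign(_ent=list(zip(raw["team"], raw["player_id"])))
    entities = list(dict.fromkeys(raw["_ent"]))
    if (BALL, BALL) not in entities:
        raise TrackingFormatError("no ball rows present (team/player label 'ball')")
    ent_pos = {e: k for k, e in enumerate(entities)}
    frame_pos = {f: k for k, f in enumerate(frame_ids)}

    xy = np.full((len(frame_ids), len(entities), 2), np.nan)
    rows = raw["frame"].map(frame_pos).to_numpy()
    cols = raw["_ent"].map(ent_pos).to_numpy()
    xy[rows, cols, 0] = raw["x"].to_numpy(dtype=float)
    xy[rows, cols, 1] = raw["y"].to_numpy(dtype=float)

    ball_col = ent_pos[(BALL, BALL)]
    missing_ball = np.isnan(xy[:, ball_col, 0])
    if missing_ball.any():
        raise TrackingFormatError(
            f"frame {frame_ids[int(np.argmax(missing_ball))]} has no ball row"
        )
    if np.isnan(xy).any():
        f, e, _ = np.argwhere(np.isnan(xy))[0]
        raise TrackingFormatError(
            f"frame {frame_ids[f]} is missing entity {entities[e]}"
        )
    return TrackingSeries(times=times, entities=entities, xy=xy, meta=meta)


def write_tracking(series: TrackingSeries, path, float_format: str = "%.3f") -> None:
    """Write a series in the long-form tracking format (mm precision)."""
    n, m = series.n_frames, len(series.entities)
    teams = [t for (t, _) in series.entities]
    pids = [p for (_, p) in series.entities]
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n), m),
            "time_s": np.repeat(series.times, m),
            "team": np.tile(teams, n),
            "player_id": np.tile(pids, n),
            "x": series.xy[:, :, 0].ravel(),
            "y": series.xy[:, :, 1].ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=float_format)


def read_events(source) -> pd.DataFrame:
    """Read and validate an event file into a time-ordered DataFrame."""
    df = pd.read_csv(source, dtype={"team": str, "player_id": str, "type": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise TrackingFormatError(f"event file missing columns {missing}")
    bad = ~df["type"].isin(EVENT_TYPES)
    if bad.any():
        raise TrackingFormatError(f"unknown event type {df['type'][bad].iloc[0]!r}")
    if np.any(np.diff(df["time_s"].to_numpy(dtype=float)) < 0):
        raise OrderingError("event times are not sorted")
    return df[EVENT_COLUMNS].copy()


def write_events(events: pd.DataFrame, path, float_format: str = "%.3f") -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# Preprocessing


def gaussian_kernel(window: int, sigma: float) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ConfigurationError("smoothing window must be odd and >= 1")
    if sigma <= 0:
        raise ConfigurationError("smoothing sigma must be positive")
    half = window // 2
    t = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (t / sigma) ** 2)
    return k / k.sum()


def smooth_positions(series: TrackingSeries, window: int = 7, sigma: float = 1.0) -> TrackingSeries:
    """Gaussian moving-average filter per coordinate.

    Edges are handled by renormalising the kernel over the available samples,
    so a constant trajectory is exactly preserved everywhere.
    """
    if window > series.n_frames:
        raise ConfigurationError(
            f"window {window} exceeds series length {series.n_frames}"
        )
    kernel = gaussian_kernel(window, sigma)
    if window == 1:
        return series.copy()
    n, m, _ = series.xy.shape
    flat = series.xy.reshape(n, m * 2)
    num = np.apply_along_axis(lambda col: np.convolve(col, kernel, mode="same"), 0, flat)
    mass = np.convolve(np.ones(n), kernel, mode="same")
    smoothed = (num / mass[:, None]).reshape(n, m, 2)
    out = series.copy()
    out.xy = smoothed
    return out


def resample(series: TrackingSeries, target_hz: float) -> TrackingSeries:
    """Linear-interpolation resampling onto a uniform grid at ``target_hz``.

    The grid starts at the first source timestamp and spans the source
    duration: ``floor(duration * target_hz) + 1`` frames.  Upsampling is
    refused.
    """
    if target_hz <= 0:
        raise ConfigurationError("target_hz must be positive")
    source_hz = 1.0 / series.dt
    if target_hz > source_hz * (1 + 1e-9):
        raise ConfigurationError(
            f"cannot upsample from {source_hz:.3f} Hz to {target_hz:.3f} Hz"
        )
    duration = float(series.times[-1] - series.times[0])
    n_out = int(np.floor(duration * target_hz + 1e-9)) + 1
    new_times = series.times[0] + np.arange(n_out) / target_hz
    n, m, _ = series.xy.shape
    flat = series.xy.reshape(n, m * 2)
    out_flat = np.empty((n_out, m * 2))
    for j in range(m * 2):
        out_flat[:, j] = np.interp(new_times, series.times, flat[:, j])
    possession = None
    if series.possession is not None:
        idx = np.clip(np.searchsorted(series.times, new_times + 1e-9) - 1, 0, n - 1)
        possession = series.possession[idx]
    return TrackingSeries(
        times=new_times,
        entities=list(series.entities),
        xy=out_flat.reshape(n_out, m, 2),
        meta=replace(series.meta, sampling_rate=float(target_hz)),
        possession=possession,
    )


def normalize_attack_direction(
    series: TrackingSeries, attacking_team: str, meta: MatchMeta | None = None
) -> TrackingSeries:
    """Reflect coordinates so ``attacking_team`` always attacks toward +x.

    Frames where the team already attacks +x are unchanged; otherwise both
    coordinates are negated (a point reflection through the pitch centre),
    which keeps all inter-player geometry intact.  The operation is an
    involution.
    """
    meta = meta or series.meta
    if attacking_team not in meta.teams:
        raise LookupError_(f"unknown team {attacking_team!r}")
    out = series.copy()
    signs = np.array(
        [meta.direction(attacking_team, meta.half_of(t)) for t in series.times],
        dtype=float,
    )
    out.xy = series.xy * signs[:, None, None]
    return out


def ball_carrier(series: TrackingSeries, frame_idx: int, team: str) -> str:
    """Player of ``team`` nearest the ball at the given frame."""
    idxs = series.team_indices(team)
    if not idxs:
        raise LookupError_(f"team {team!r} has no tracked players")
    ball = series.xy[frame_idx, series.ball_index]
    d = np.linalg.norm(series.xy[frame_idx, idxs] - ball, axis=1)
    return series.entities[idxs[int(np.argmin(d))]][1]
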