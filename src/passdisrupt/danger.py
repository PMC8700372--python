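"""Danger value of pass receptions and danger-based attack success.

The danger of a ball reception (0-1) is a zone value from a grid covering
the last 35 m in front of the opponent goal — higher the closer to the goal
— minus a deduction for nearby goal-side defenders, clipped to [0, 1].  An
attack is successful iff its peak reception danger exceeds 0.

All geometry here assumes attack-normalised coordinates (the attacking team
plays toward ``(+pitch_length/2, 0)``); :func:`danger_at_reception` performs
the normalisation itself from match metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .possession import Attack, PassRecord
from .tracking import MatchMeta, TrackingSeries, ball_carrier
from .errors import DataGapError


@dataclass(frozen=True)
class DangerConfig:
    """Concrete parameters of the zone/pressure model.

    zone_depth        depth of the scoring zone in front of the goal [m]
    cell_size         grid cell edge length [m]
    lateral_half_width  half-width of the lateral decay [m]; None = pitch_width/4
    pressure_radius   radius within which defenders exert pressure [m]
    pressure_weight   maximum deduction per defender
    goal_side_window_deg  half-angle of the goal-side sector around the
                      ball-to-goal bearing [degrees]
    """

    zone_depth: float = 35.0
    cell_size: float = 5.0
    lateral_half_width: float | None = None
    pressure_radius: float = 4.0
    pressure_weight: float = 0.5
    goal_side_window_deg: float = 90.0

    def __post_init__(self):
        if min(self.zone_depth, self.cell_size, self.pressure_radius) <= 0:
            raise ValueError("zone_depth, cell_size and pressure_radius must be positive")
        if self.pressure_weight < 0 or self.goal_side_window_deg <= 0:
            raise ValueError("invalid pressure parameters")

    def half_width(self, meta: MatchMeta) -> float:
        return self.lateral_half_width if self.lateral_half_width is not None else meta.pitch_width / 4


@dataclass
class DangerSample:
    """Danger of one ball reception."""

    time: float
    carrier: str | None
    zone: float
    pressure: float
    danger: float


@dataclass
class AttackOutcome:
    attack_id: str
    peak_danger: float
    success: bool


def zone_value(pos: np.ndarray, meta: MatchMeta, config: DangerConfig | None = None) -> float:
    """Grid zone value of a position (attack-normalised coordinates).

    Zero outside the zone (further than ``zone_depth`` from the goal line);
    inside, the containing cell carries its maximal ramp value: a linear ramp
    ``1 - d/zone_depth`` in the distance ``d`` from the goal line times a
    lateral factor ``max(0, 1 - |y| / (2 * half_width))``, both evaluated at
    the cell edge nearest the goal / nearest the centre line.
    """
    config = config or DangerConfig()
    x, y = float(pos[0]), float(pos[1])
    d_long = meta.pitch_length / 2 - x
    if d_long < 0 or d_long > config.zone_depth:
        return 0.0
    cell = config.cell_size
    d_min = np.floor(d_long / cell) * cell
    y_min = np.floor(abs(y) / cell) * cell
    ramp = max(0.0, 1.0 - d_min / config.zone_depth)
    lateral = max(0.0, 1.0 - y_min / (2 * config.half_width(meta)))
    return float(ramp * lateral)


def pressure_deduction(
    ball_pos: np.ndarray,
    defender_positions: np.ndarray,
    meta: MatchMeta,
    config: DangerConfig | None = None,
) -> float:
    """Summed deduction from defenders close to the ball on the goal side.

    A defender within ``pressure_radius`` of the ball whose bearing is inside
    the goal-side angular window contributes ``w_max * (rho - dist) / rho``.
    """
    config = config or DangerConfig()
    defenders = np.asarray(defender_positions, dtype=float).reshape(-1, 2)
    if defenders.size == 0:
        return 0.0
    ball = np.asarray(ball_pos, dtype=float)
    goal = np.array([meta.pitch_length / 2, 0.0])
    to_goal = goal - ball
    rel = defenders - ball
    dist = np.linalg.norm(rel, axis=1)
    rho = config.pressure_radius
    near = dist < rho
    if not near.any():
        return 0.0
    if np.linalg.norm(to_goal) < 1e-9:
        goal_side = np.ones_like(near)  # ball on the goal line: all directions count
    else:
        cos_lim = np.cos(np.deg2rad(config.goal_side_window_deg))
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = rel @ to_goal / (dist * np.linalg.norm(to_goal))
        cosang = np.where(dist < 1e-9, 1.0, cosang)  # defender on the ball: full pressure
        goal_side = cosang >= cos_lim - 1e-12
    mask = near & goal_side
    return float(np.sum(config.pressure_weight * (rho - dist[mask]) / rho))


def danger_at_reception(
    series: TrackingSeries,
    pass_record: PassRecord,
    meta: MatchMeta | None = None,
    config: DangerConfig | None = None,
) -> DangerSample | None:
    """Danger value at the reception of a completed pass.

    Returns ``None`` (sample flagged missing) when no tracking frame exists
    near the reception time.
    """
    meta = meta or series.meta
    config = config or DangerConfig()
    if not pass_record.completed:
        return None
    try:
        i = series.frame_index_at(pass_record.t_reception)
    except DataGapError:
        return None
    sign = meta.direction(pass_record.team, meta.half_of(pass_record.t_reception))
    reception = np.asarray(pass_record.reception, dtype=float) * sign
    defending = meta.opponent(pass_record.team)
    def_idx = series.team_indices(defending)
    defenders = series.xy[i, def_idx, :] * sign
    zone = zone_value(reception, meta, config)
    pressure = pressure_deduction(reception, defenders, meta, config) if zone > 0 else 0.0
    danger = float(np.clip(zone - pressure, 0.0, 1.0))
    try:
        carrier = ball_carrier(series, i, pass_record.team)
    except Exception:
        carrier = None
    return DangerSample(
        time=float(pass_record.t_reception),
        carrier=carrier,
        zone=zone,
        pressure=pressure,
        danger=danger,
    )


def classify_attack(attack: Attack, samples: list[DangerSample]) -> AttackOutcome:
    """Success iff the peak reception danger of the attack is strictly > 0."""
    samples = [s for s in samples if s is not None]
    if not samples:
        raise InsufficientDataError(f"attack {attack.attack_id} has no danger samples")
    peak = max(s.danger for s in samples)
    return AttackOutcome(attack_id=attack.attack_id, peak_danger=peak, success=peak > 0)


def outcomes_table(outcomes: list[AttackOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "attack_id": [o.attack_id for o in outcomes],
            "peak_danger": [o.peak_danger for o in outcomes],
            "success": [int(o.success) for o in outcomes],
        }
    )
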