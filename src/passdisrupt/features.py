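"""Geometric pass descriptors and the per-attack sequence table.

Pass length is the Euclidean distance between release and reception,
velocity is length over flight time, and the pass angle is the full-circle
direction of the displacement vector relative to the attacking direction
(0 deg = straight toward the opponent goal, computed with the two-argument
arctangent so forward and backward passes are distinguished; the classic
slope form arctan(dy/dx) is its restriction to (-90, 90) deg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .danger import AttackOutcome
from .disruption import DDefResult
from .errors import ConsistencyError, DegenerateInputError
from .possession import Attack, PassRecord, last_k_passes

PASS_INDEX_RANGE = (1, 2, 3, 4)


@dataclass
class PassFeatures:
    """Length [m], velocity [m/s] and direction of one completed pass."""

    length: float
    velocity: float
    slope: float
    angle: float  # degrees in (-180, 180], 0 = attacking direction

    @property
    def L_pass(self) -> float:
        return self.length

    @property
    def V_pass(self) -> float:
        return self.velocity


def pass_length(pass_record: PassRecord) -> float:
    delta = np.asarray(pass_record.reception) - np.asarray(pass_record.release)
    return float(np.hypot(delta[0], delta[1]))


def pass_velocity(pass_record: PassRecord) -> float:
    dt = pass_record.t_reception - pass_record.t_pass
    if dt <= 0:
        raise ConsistencyError(f"non-positive pass flight time {dt}")
    return pass_length(pass_record) / dt


def pass_angle(pass_record: PassRecord, direction_sign: int = 1) -> float:
    """Full-circle pass direction in degrees, 0 = toward the opponent goal.

    ``direction_sign`` is the attacking direction of the passing team (+1 or
    -1); with -1 the displacement is point-reflected into the normalised
    frame before the angle is taken.
    """
    delta = (np.asarray(pass_record.reception) - np.asarray(pass_record.release)) * direction_sign
    if np.hypot(delta[0], delta[1]) == 0:
        raise DegenerateInputError("zero-length pass has no direction")
    ang = float(np.degrees(np.arctan2(delta[1], delta[0])))
    return 180.0 if ang == -180.0 else ang


def pass_features(pass_record: PassRecord, direction_sign: int = 1) -> PassFeatures:
    length = pass_length(pass_record)
    velocity = pass_velocity(pass_record)
    delta = np.asarray(pass_record.reception) - np.asarray(pass_record.release)
    slope = float(delta[1] / delta[0]) if delta[0] != 0 else float("inf") * np.sign(delta[1] or 1)
    angle = pass_angle(pass_record, direction_sign) if length > 0 else float("nan")
    return PassFeatures(length=length, velocity=velocity, slope=slope, angle=angle)


def build_sequence_table(
    attacks: list[Attack],
    ddef_results: dict[tuple[str, int], DDefResult | None],
    features: dict[tuple[str, int], PassFeatures | None],
    outcomes: dict[str, AttackOutcome],
) -> pd.DataFrame:
    """One row per attack with success label and last-four-pass measures.

    ``ddef_results`` and ``features`` are keyed by ``(attack_id, pass_index)``
    with pass index 1 = last pass.  Mean/max columns aggregate over the
    available (non-missing) last-four passes; attacks with only three passes
    leave the pass-4 cells empty.
    """
    rows = []
    for attack in sorted(attacks, key=lambda a: a.attack_id):
        outcome = outcomes.get(attack.attack_id)
        row: dict[str, object] = {
            "attack_id": attack.attack_id,
            "team": attack.team,
            "success": int(outcome.success) if outcome is not None else np.nan,
            "peak_danger": outcome.peak_danger if outcome is not None else np.nan,
            "duration_s": attack.duration,
            "n_passes": attack.n_passes,
        }
        ddef_vals, l_vals, v_vals = [], [], []
        for idx in PASS_INDEX_RANGE:
            dres = ddef_results.get((attack.attack_id, idx))
            feat = features.get((attack.attack_id, idx))
            row[f"ddef_pass{idx}"] = dres.ddef if dres is not None else np.nan
            row[f"L_pass{idx}"] = feat.length if feat is not None else np.nan
            row[f"V_pass{idx}"] = feat.velocity if feat is not None else np.nan
            row[f"alpha_pass{idx}"] = feat.angle if feat is not None else np.nan
            if dres is not None:
                ddef_vals.append(dres.ddef)
            if feat is not None:
                l_vals.append(feat.length)
                v_vals.append(feat.velocity)
        row["ddef_mean"] = float(np.mean(ddef_vals)) if ddef_vals else np.nan
        row["ddef_max"] = float(np.max(ddef_vals)) if ddef_vals else np.nan
        row["L_mean"] = float(np.mean(l_vals)) if l_vals else np.nan
        row["L_max"] = float(np.max(l_vals)) if l_vals else np.nan
        row["V_mean"] = float(np.mean(v_vals)) if v_vals else np.nan
        row["V_max"] = float(np.max(v_vals)) if v_vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def features_for_attack(attack: Attack, meta, k: int = 4) -> dict[tuple[str, int], PassFeatures]:
    """Features of the last ``k`` completed passes of one attack."""
    out = {}
    for idx, rec in enumerate(last_k_passes(attack, k), start=1):
        sign = meta.direction(attack.team, meta.half_of(rec.t_pass))
        out[(attack.attack_id, idx)] = pass_features(rec, direction_sign=sign)
    return out
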