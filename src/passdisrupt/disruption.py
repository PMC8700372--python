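"""Defensive-organisation states and the D-Def disruption score of a pass.

The defensive organisation at an instant is summarised by ten quantities:
the full-team centroid (C_x, C_y), the three line centroids (C_xdef/C_ydef,
C_xmid/C_ymid, C_xatt/C_yatt), the convex-hull surface area S_area and the
spread S_spread (Frobenius norm of the centred position matrix).  D-Def
scores a pass by the change of these quantities between the moment the pass
is played and a fixed horizon (3 s) later, combined through fixed
principal-component loadings:

    PC1 = -0.46 dC_x + 0.26 dC_y - 0.43 dC_xdef + 0.24 dC_ydef
          - 0.43 dC_xmid + 0.24 dC_ymid - 0.41 dC_xatt + 0.24 dC_yatt
    PC2 = -0.26 dC_x - 0.47 dC_y - 0.24 dC_xdef - 0.43 dC_ydef
          - 0.25 dC_xmid - 0.43 dC_ymid - 0.24 dC_xatt - 0.40 dC_yatt
    PC3 =  0.71 dS_area + 0.71 dS_spread
    D-Def = |PC1| + |PC2| + |PC3|,  clipped to [0, 150]

Changes are absolute values by default (disruption magnitude); a signed mode
is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DataGapError, OrderingError, PassDisruptError
from .formations import LineAssignment
from .possession import PassRecord
from .tracking import TrackingFrame, TrackingSeries

#: Ordered names of the organisation components.
ORG_COMPONENTS = (
    "C_x",
    "C_y",
    "C_xdef",
    "C_ydef",
    "C_xmid",
    "C_ymid",
    "C_xatt",
    "C_yatt",
    "S_area",
    "S_spread",
)

#: Fixed principal-component loadings over the component deltas.
PC1_LOADINGS = dict(
    zip(ORG_COMPONENTS, (-0.46, 0.26, -0.43, 0.24, -0.43, 0.24, -0.41, 0.24, 0.0, 0.0))
)
PC2_LOADINGS = dict(
    zip(ORG_COMPONENTS, (-0.26, -0.47, -0.24, -0.43, -0.25, -0.43, -0.24, -0.40, 0.0, 0.0))
)
PC3_LOADINGS = dict(
    zip(ORG_COMPONENTS, (0.0,) * 8 + (0.71, 0.71))
)

DDEF_MAX = 150.0


@dataclass
class OrgState:
    """Snapshot of a team's defensive organisation at one instant."""

    time: float
    C_x: float
    C_y: float
    C_xdef: float
    C_ydef: float
    C_xmid: float
    C_ymid: float
    C_xatt: float
    C_yatt: float
    S_area: float
    S_spread: float

    def component(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class OrgDelta:
    """Component-wise change between two organisation states."""

    components: dict[str, float]
    mode: str = "unsigned"  # or "signed"
    t0: float = 0.0
    t1: float = 0.0

    def __post_init__(self):
        missing = [c for c in ORG_COMPONENTS if c not in self.components]
        if missing:
            raise PassDisruptError(f"incomplete delta, missing components {missing}")
        if self.mode == "unsigned" and any(v < 0 for v in self.components.values()):
            raise PassDisruptError("unsigned delta has negative components")

    @classmethod
    def zero(cls) -> "OrgDelta":
        return cls(components={c: 0.0 for c in ORG_COMPONENTS})


@dataclass
class DDefResult:
    """Component scores and the composite disruption score of one pass."""

    PC1: float
    PC2: float
    PC3: float
    ddef: float
    horizon: float = 3.0
    pass_ref: PassRecord | None = None


def convex_hull_area(points: np.ndarray) -> float:
    """Area of the smallest convex hull of 2-D points; 0 for degenerate sets."""
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        return 0.0
    try:
        return float(ConvexHull(points).volume)  # "volume" is area in 2-D
    except QhullError:
        return 0.0  # collinear


def spread(points: np.ndarray) -> float:
    """Frobenius norm of the centred position matrix: root-sum-of-squared
    player distances from the team centroid."""
    points = np.asarray(points, dtype=float)
    return float(np.linalg.norm(points - points.mean(axis=0)))


def org_state(frame: TrackingFrame, assignment: LineAssignment) -> OrgState:
    """Compute the organisation snapshot for the assigned (outfield) players."""
    team = assignment.team
    pts = {}
    for pid in assignment.labels:
        key = (team, pid)
        if key not in frame.positions:
            raise DataGapError(f"player {key} missing from frame at t={frame.time:.3f}")
        pts[pid] = frame.positions[key]
    all_pts = np.array([pts[p] for p in assignment.labels])
    centroid = all_pts.mean(axis=0)
    line_centroids = {}
    for line in ("DEF", "MID", "ATT"):
        players = assignment.players_in(line)
        line_pts = np.array([pts[p] for p in players])
        line_centroids[line] = line_pts.mean(axis=0)
    return OrgState(
        time=frame.time,
        C_x=float(centroid[0]),
        C_y=float(centroid[1]),
        C_xdef=float(line_centroids["DEF"][0]),
        C_ydef=float(line_centroids["DEF"][1]),
        C_xmid=float(line_centroids["MID"][0]),
        C_ymid=float(line_centroids["MID"][1]),
        C_xatt=float(line_centroids["ATT"][0]),
        C_yatt=float(line_centroids["ATT"][1]),
        S_area=convex_hull_area(all_pts),
        S_spread=spread(all_pts),
    )


def org_delta(s0: OrgState, s1: OrgState, mode: str = "unsigned") -> OrgDelta:
    """Component-wise change s1 - s0 (absolute values in unsigned mode)."""
    if s1.time <= s0.time:
        raise OrderingError(f"state times out of order: {s0.time} -> {s1.time}")
    comps = {c: s1.component(c) - s0.component(c) for c in ORG_COMPONENTS}
    if mode == "unsigned":
        comps = {c: abs(v) for c, v in comps.items()}
    elif mode != "signed":
        raise ValueError(f"unknown delta mode {mode!r}")
    return OrgDelta(components=comps, mode=mode, t0=s0.time, t1=s1.time)


def ddef(delta: OrgDelta, horizon: float = 3.0, pass_ref: PassRecord | None = None) -> DDefResult:
    """Evaluate the fixed loadings on a delta and form the composite score."""
    vals = delta.components
    if any(not np.isfinite(vals[c]) for c in ORG_COMPONENTS):
        raise PassDisruptError("delta contains non-finite components")
    pc1 = sum(PC1_LOADINGS[c] * vals[c] for c in ORG_COMPONENTS)
    pc2 = sum(PC2_LOADINGS[c] * vals[c] for c in ORG_COMPONENTS)
    pc3 = sum(PC3_LOADINGS[c] * vals[c] for c in ORG_COMPONENTS)
    score = min(abs(pc1) + abs(pc2) + abs(pc3), DDEF_MAX)
    return DDefResult(PC1=pc1, PC2=pc2, PC3=pc3, ddef=score, horizon=horizon, pass_ref=pass_ref)


def ddef_for_pass(
    series: TrackingSeries,
    pass_record: PassRecord,
    assignment: LineAssignment,
    horizon: float = 3.0,
    mode: str = "unsigned",
) -> DDefResult | None:
    """D-Def of a pass: organisation change of the defending team between the
    pass moment and ``horizon`` seconds later.

    ``assignment`` must belong to the team defending against the pass.
    Returns ``None`` when either instant has no tracking frame within half a
    frame period, or when the horizon crosses a half-time boundary (play is
    not continuous there).
    """
    t0, t1 = pass_record.t_pass, pass_record.t_pass + horizon
    meta = series.meta
    if meta.half_of(t0) != meta.half_of(t1):
        return None
    try:
        i0 = series.frame_index_at(t0)
        i1 = series.frame_index_at(t1)
    except DataGapError:
        return None
    s0 = org_state(series.frame(i0), assignment)
    s1 = org_state(series.frame(i1), assignment)
    return ddef(org_delta(s0, s1, mode=mode), horizon=horizon, pass_ref=pass_record)
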