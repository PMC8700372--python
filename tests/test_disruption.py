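import numpy as np
import pytest

from passdisrupt import MatchMeta, OrgDelta, ddef, org_delta, org_state
from passdisrupt.disruption import (
    ORG_COMPONENTS,
    PC1_LOADINGS,
    PC2_LOADINGS,
    PC3_LOADINGS,
    convex_hull_area,
    ddef_for_pass,
)
from passdisrupt.errors import DataGapError, OrderingError
from passdisrupt.formations import LineAssignment
from passdisrupt.possession import PassRecord
from passdisrupt.tracking import TrackingFrame

from conftest import make_series


def simple_assignment(n_def=1, n_mid=1, n_att=1, team="away"):
    labels = {}
    i = 2
    for line, n in (("DEF", n_def), ("MID", n_mid), ("ATT", n_att)):
        for _ in range(n):
            labels[f"p{i}"] = line
            i += 1
    return LineAssignment(
        team=team, phase="out_of_possession", labels=labels,
        centers=np.array([-30.0, -10.0, 10.0]),
        sizes=(n_def, n_mid, n_att),
    )


def frame_from(points, team="away", time=0.0):
    positions = {(team, f"p{i + 2}"): np.asarray(p, float) for i, p in enumerate(points)}
    return TrackingFrame(time=time, positions=positions, ball=np.zeros(2))


# ---------------------------------------------------------------------------
# hull oracle: gift wrapping + shoelace, coded independently of Qhull


def _hull_area_oracle(points):
    pts = np.unique(np.round(np.asarray(points, float), 12), axis=0)
    if len(pts) < 3:
        return 0.0
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = 0 if cur != 0 else 1
        for j in range(len(pts)):
            if j == cur:
                continue
            u, v = pts[j] - pts[cur], pts[cand] - pts[cur]
            cross = u[0] * v[1] - u[1] * v[0]
            if cand == cur or cross > 0 or (
                cross == 0
                and np.linalg.norm(pts[j] - pts[cur]) > np.linalg.norm(pts[cand] - pts[cur])
            ):
                cand = j
        if cand == start:
            break
        hull.append(cand)
        if len(hull) > len(pts):
            return 0.0  # degenerate
    if len(hull) < 3:
        return 0.0
    poly = pts[hull]
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


class TestOrgState:
    def test_collinear_players_have_zero_area(self):
        state = org_state(frame_from([(0, 0), (10, 0), (20, 0)]), simple_assignment())
        assert state.C_x == 10 and state.C_y == 0
        assert state.S_area == 0.0

    def test_unit_square_area_and_centroid(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        state = org_state(frame_from(pts), simple_assignment(2, 1, 1))
        assert state.S_area == pytest.approx(1.0, abs=1e-12)
        assert (state.C_x, state.C_y) == (0.5, 0.5)

    def test_spread_of_two_opposite_players_is_root_two(self):
        from passdisrupt.disruption import spread

        assert spread([(-1.0, 0.0), (1.0, 0.0)]) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_two_player_spread_is_root_two(self):
        # only DEF/MID lines occupied; spread over both players
        assignment = LineAssignment(
            team="away", phase="out_of_possession",
            labels={"p2": "DEF", "p3": "MID", "p4": "ATT"},
            centers=np.array([-1.0, 0.0, 1.0]), sizes=(1, 1, 1),
        )
        state = org_state(frame_from([(-1, 0), (1, 0), (0, 3)]), assignment)
        spread_oracle = np.sqrt(((np.array([[-1, 0], [1, 0], [0, 3.0]])
                                  - np.array([0, 1.0])) ** 2).sum())
        assert state.S_spread == pytest.approx(spread_oracle, abs=1e-12)

    def test_missing_player_names_the_player(self):
        with pytest.raises(DataGapError, match="p4"):
            org_state(frame_from([(0, 0), (1, 1)]), simple_assignment())

    def test_hull_area_matches_brute_force_oracle_on_random_points(self):
        rng = np.random.default_rng(3)
        for n in (3, 4, 5, 6, 7, 8):
            for _ in range(40):
                pts = rng.uniform(-30, 30, size=(n, 2))
                assert convex_hull_area(pts) == pytest.approx(
                    _hull_area_oracle(pts), abs=1e-9
                )


class TestOrgDelta:
    def _states(self, shift=(0.0, 0.0)):
        f0 = frame_from([(0, 0), (10, 0), (20, 5)], time=0.0)
        f1 = frame_from([(p[0] + shift[0], p[1] + shift[1]) for p in [(0, 0), (10, 0), (20, 5)]],
                        time=3.0)
        a = simple_assignment()
        return org_state(f0, a), org_state(f1, a)

    def test_identical_states_give_zero_delta(self):
        s0, s1 = self._states()
        delta = org_delta(s0, s1)
        assert all(v == 0 for v in delta.components.values())

    def test_unsigned_takes_absolute_values_and_signed_preserves(self):
        s0, s1 = self._states(shift=(-2.0, 0.0))
        assert org_delta(s0, s1, mode="unsigned").components["C_x"] == pytest.approx(2.0)
        assert org_delta(s0, s1, mode="signed").components["C_x"] == pytest.approx(-2.0)

    def test_out_of_order_states_raise(self):
        s0, s1 = self._states()
        with pytest.raises(OrderingError):
            org_delta(s1, s0)


def delta_with(**kw):
    comps = {c: 0.0 for c in ORG_COMPONENTS}
    comps.update(kw)
    return OrgDelta(components=comps)


class TestDDefScore:
    def test_zero_delta_scores_zero(self):
        res = ddef(OrgDelta.zero())
        assert res.PC1 == res.PC2 == res.PC3 == res.ddef == 0.0

    def test_unit_team_centroid_impulse(self):
        res = ddef(delta_with(C_x=1.0))
        assert res.PC1 == pytest.approx(-0.46, abs=1e-12)
        assert res.PC2 == pytest.approx(-0.26, abs=1e-12)
        assert res.ddef == pytest.approx(0.72, abs=1e-12)

    def test_unit_area_and_spread_impulse(self):
        res = ddef(delta_with(S_area=1.0, S_spread=1.0))
        assert res.PC3 == pytest.approx(1.42, abs=1e-12)
        assert res.ddef == pytest.approx(1.42, abs=1e-12)

    def test_score_is_clipped_at_150(self):
        res = ddef(delta_with(S_area=200.0, S_spread=200.0))
        assert res.ddef == 150.0

    def test_monotone_in_every_unsigned_component(self):
        base = {c: 0.5 for c in ORG_COMPONENTS}
        base_score = ddef(OrgDelta(components=base)).ddef
        for c in ORG_COMPONENTS:
            bumped = dict(base)
            bumped[c] += 1.0
            assert ddef(OrgDelta(components=bumped)).ddef >= base_score - 1e-12

    def test_homogeneity_on_centroid_terms(self):
        centroid = {c: (0.8 if c.startswith("C") else 0.0) for c in ORG_COMPONENTS}
        s1 = ddef(OrgDelta(components=centroid)).ddef
        scaled = {c: 3.0 * v for c, v in centroid.items()}
        assert ddef(OrgDelta(components=scaled)).ddef == pytest.approx(3.0 * s1, rel=1e-12)

    def test_zero_iff_all_components_zero(self):
        for c in ORG_COMPONENTS:
            assert ddef(delta_with(**{c: 0.3})).ddef > 0


class TestDDefForPass:
    def _series(self, move=(0.0, 0.0), both_instants_translation=None):
        times = np.arange(0, 41) / 10.0
        data = {}
        base = {"p2": (-30, 0), "p3": (-10, 5), "p4": (10, -5)}
        for pid, (x, y) in base.items():
            traj = []
            for t in times:
                w = min(max(t / 3.0, 0.0), 1.0)
                px, py = x + move[0] * w, y + move[1] * w
                if both_instants_translation:
                    px += both_instants_translation[0]
                    py += both_instants_translation[1]
                traj.append((px, py))
            data[("away", pid)] = traj
        return make_series(data, times)

    def _pass(self):
        return PassRecord(
            passer="p2", team="home", t_pass=0.0, release=np.zeros(2),
            receiver="p3", t_reception=1.0, reception=np.array([5.0, 0.0]),
            completed=True,
        )

    def test_static_defense_scores_zero(self):
        res = ddef_for_pass(self._series(), self._pass(), simple_assignment())
        assert res.ddef == 0.0

    def test_global_translation_leaves_score_unchanged(self):
        r1 = ddef_for_pass(self._series(move=(2, 1)), self._pass(), simple_assignment())
        r2 = ddef_for_pass(
            self._series(move=(2, 1), both_instants_translation=(7, -4)),
            self._pass(), simple_assignment(),
        )
        assert r1.ddef == pytest.approx(r2.ddef, abs=1e-12)

    def test_rigid_shift_scores_coefficient_sum_per_metre(self):
        # hand evaluation of the loadings for a rigid (-1, 0) m shift: all
        # four x-centroid deltas equal 1, so |PC1| + |PC2| is the sum of the
        # x-coefficient magnitudes
        expected_per_m = sum(
            abs(PC1_LOADINGS[c]) for c in ("C_x", "C_xdef", "C_xmid", "C_xatt")
        ) + sum(abs(PC2_LOADINGS[c]) for c in ("C_x", "C_xdef", "C_xmid", "C_xatt"))
        assert expected_per_m == pytest.approx(2.72, abs=1e-12)
        res = ddef_for_pass(self._series(move=(-1.0, 0.0)), self._pass(), simple_assignment())
        assert res.ddef == pytest.approx(expected_per_m, abs=1e-9)

    def test_horizon_past_series_end_is_flagged_missing(self):
        series = self._series()
        rec = self._pass()
        rec.t_pass, rec.t_reception = 1.0, 2.0  # window ends inside the series
        assert ddef_for_pass(series, rec, simple_assignment(), horizon=3.0) is not None
        rec.t_pass, rec.t_reception = 2.0, 3.0  # window extends past the end
        assert ddef_for_pass(series, rec, simple_assignment(), horizon=3.0) is None
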