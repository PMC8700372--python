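import numpy as np
import pandas as pd
import pytest
from scipy import special, stats as sps

from passdisrupt.errors import DegenerateInputError, InsufficientDataError
from passdisrupt.stats import (
    angle_distribution,
    build_report,
    cohens_d,
    compare_groups,
    compare_groups_from_summary,
    holm_correction,
    mixed_anova,
    resultant_length,
    watson_williams,
)


def make_table(dv_by_group, n_per_group, rng, extra_cols=True):
    """Sequence-table stub: per-group generator for the four pass columns."""
    rows = []
    for g in (0, 1):
        for i in range(n_per_group):
            vals = dv_by_group(g, rng)
            row = {f"ddef_pass{j + 1}": vals[j] for j in range(4)}
            row["success"] = g
            row["attack_id"] = f"g{g}a{i}"
            if extra_cols:
                row.update(
                    duration_s=float(rng.gamma(4, 5)), n_passes=int(rng.integers(3, 10)),
                    ddef_mean=np.mean(vals), ddef_max=np.max(vals),
                )
                for j in range(4):
                    row[f"L_pass{j + 1}"] = float(rng.normal(18, 6))
                    row[f"V_pass{j + 1}"] = float(rng.normal(12, 3))
                    row[f"alpha_pass{j + 1}"] = float(rng.normal(40, 30))
                Ls = [row[f"L_pass{j + 1}"] for j in range(4)]
                Vs = [row[f"V_pass{j + 1}"] for j in range(4)]
                row.update(L_mean=np.mean(Ls), L_max=np.max(Ls),
                           V_mean=np.mean(Vs), V_max=np.max(Vs))
            rows.append(row)
    return pd.DataFrame(rows)


class TestCohensD:
    @pytest.mark.parametrize(
        "n1,m1,s1,n2,m2,s2,printed",
        [
            (5529, 7.14, 4.39, 7565, 5.26, 2.92, 0.52),
            (5128, 29.96, 16.02, 7061, 28.16, 14.20, 0.12),
            (5145, 28.69, 15.13, 7056, 25.51, 12.63, 0.23),
        ],
    )
    def test_pooled_d_from_summary_statistics(self, n1, m1, s1, n2, m2, s2, printed):
        assert round(cohens_d(n1, m1, s1, n2, m2, s2), 2) == printed

    def test_equal_means_give_zero(self):
        assert cohens_d(10, 5.0, 2.0, 12, 5.0, 3.0) == 0.0

    def test_zero_pooled_sd_with_unequal_means_is_undefined(self):
        with pytest.raises(DegenerateInputError):
            cohens_d(10, 5.0, 0.0, 12, 6.0, 0.0)


class TestHolm:
    def test_step_down_worked_example(self):
        adjusted, reject = holm_correction([0.01, 0.02, 0.04])
        np.testing.assert_allclose(adjusted, [0.03, 0.04, 0.04])
        assert reject.all()

    def test_single_p_is_unchanged(self):
        adjusted, _ = holm_correction([0.013])
        assert adjusted[0] == pytest.approx(0.013)

    def test_adjusted_values_monotone_in_sorted_order(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(2, 12))
            adj, _ = holm_correction(p)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_holm_rejects_at_least_as_much_as_bonferroni(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.uniform(0, 0.2, rng.integers(2, 10))
            _, holm_rej = holm_correction(p)
            bonf_rej = p < 0.05 / len(p)
            assert np.all(holm_rej | ~bonf_rej)


class TestCompareGroups:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_groups(x, x.copy())
        assert res.t == 0.0 and res.p == pytest.approx(1.0) and res.cohen_d == 0.0

    def test_pooled_t_matches_closed_form(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 25), rng.normal(0.5, 1, 30)
        res = compare_groups(x, y)
        assert not res.welch
        sp = np.sqrt(((24 * x.var(ddof=1)) + (29 * y.var(ddof=1))) / 53)
        t_hand = (x.mean() - y.mean()) / (sp * np.sqrt(1 / 25 + 1 / 30))
        assert res.t == pytest.approx(t_hand, abs=1e-10)
        assert res.df == 53

    def test_levene_switches_to_welch_under_unequal_variance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 200), rng.normal(0, 6, 200)
        res = compare_groups(x, y)
        assert res.welch and res.levene_p < 0.05
        assert res.df != 398  # Welch df is non-integer and smaller

    def test_pooled_p_close_to_permutation_oracle(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0.0, 1, 30), rng.normal(0.6, 1, 30)
        res = compare_groups(x, y)
        pooled = np.concatenate([x, y])
        n_perm = 20000
        idx = np.argsort(rng.random((n_perm, 60)), axis=1)
        perm = pooled[idx]
        diffs = perm[:, :30].mean(axis=1) - perm[:, 30:].mean(axis=1)
        p_perm = (np.abs(diffs) >= abs(x.mean() - y.mean())).mean()
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.004
        assert res.p == pytest.approx(p_perm, abs=mc_err)

    def test_summary_path_reproduces_raw_pooled_test(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 40), rng.normal(0.3, 1, 35)
        raw = compare_groups(x, y)
        summ = compare_groups_from_summary(
            40, x.mean(), x.std(ddof=1), 35, y.mean(), y.std(ddof=1)
        )
        assert summ.t == pytest.approx(raw.t, abs=1e-10)
        assert summ.p == pytest.approx(raw.p, abs=1e-10)

    def test_tiny_group_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0], [1.0, 2.0])


def _hand_mixed_ss(y):
    """Split-plot sums-of-squares decomposition for balanced (a, n, b) data."""
    a, n, b = y.shape
    grand = y.mean()
    group_means, subj_means = y.mean(axis=(1, 2)), y.mean(axis=2)
    b_means, cell_means = y.mean(axis=(0, 1)), y.mean(axis=1)
    SS_A = n * b * ((group_means - grand) ** 2).sum()
    SS_subj = b * ((subj_means - group_means[:, None]) ** 2).sum()
    SS_B = a * n * ((b_means - grand) ** 2).sum()
    SS_AB = n * ((cell_means - group_means[:, None] - b_means[None, :] + grand) ** 2).sum()
    SS_err = ((y - grand) ** 2).sum() - SS_A - SS_subj - SS_B - SS_AB
    df_A, df_subj = a - 1, a * (n - 1)
    df_B, df_AB = b - 1, (a - 1) * (b - 1)
    df_err = df_subj * df_B
    F = (
        (SS_A / df_A) / (SS_subj / df_subj),
        (SS_B / df_B) / (SS_err / df_err),
        (SS_AB / df_AB) / (SS_err / df_err),
    )
    np2 = (SS_A / (SS_A + SS_subj), SS_B / (SS_B + SS_err), SS_AB / (SS_AB + SS_err))
    return F, np2, (SS_A, SS_subj, SS_B, SS_AB, SS_err)


class TestMixedAnova:
    def _table(self, y):
        a, n, b = y.shape
        df = pd.DataFrame({f"ddef_pass{j + 1}": y[:, :, j].ravel() for j in range(b)})
        df["success"] = np.repeat([0, 1], n)
        df["attack_id"] = [f"s{i}" for i in range(a * n)]
        return df

    def test_matches_hand_sums_of_squares_oracle(self):
        rng = np.random.default_rng(5)
        y = rng.normal(10, 3, size=(2, 3, 4)) + np.arange(4) * 1.5
        y[1] += 2.0
        res = mixed_anova(self._table(y), "ddef")
        (F_A, F_B, F_AB), (n_A, n_B, n_AB), _ = _hand_mixed_ss(y)
        assert res.effects["success"].F == pytest.approx(F_A, abs=1e-8)
        assert res.effects["sequence"].F == pytest.approx(F_B, abs=1e-8)
        assert res.effects["interaction"].F == pytest.approx(F_AB, abs=1e-8)
        assert res.effects["success"].partial_eta_sq == pytest.approx(n_A, abs=1e-8)
        assert res.effects["sequence"].partial_eta_sq == pytest.approx(n_B, abs=1e-8)
        assert res.effects["interaction"].partial_eta_sq == pytest.approx(n_AB, abs=1e-8)

    def test_sums_of_squares_add_to_total_on_balanced_data(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(2, 8, 4))
        _, _, parts = _hand_mixed_ss(y)
        assert sum(parts) == pytest.approx(((y - y.mean()) ** 2).sum(), rel=1e-12)

    def test_constant_dv_has_zero_effects(self):
        y = np.full((2, 3, 4), 7.0)
        res = mixed_anova(self._table(y), "ddef")
        for eff in res.effects.values():
            assert eff.F == 0.0 and eff.partial_eta_sq == 0.0

    def test_incomplete_cases_are_dropped(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(2, 10, 4))
        table = self._table(y)
        table.loc[0, "ddef_pass4"] = np.nan
        res = mixed_anova(table, "ddef")
        assert res.n_success + res.n_unsuccess == 19

    def test_single_attack_per_group_is_insufficient(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(2, 1, 4))
        with pytest.raises(InsufficientDataError):
            mixed_anova(self._table(y), "ddef")


def _ww_oracle(a_deg, b_deg):
    """Independent coding of the Watson-Williams F statistic."""
    aa, bb = np.deg2rad(np.asarray(a_deg)), np.deg2rad(np.asarray(b_deg))
    n1, n2 = len(aa), len(bb)
    N = n1 + n2
    R1 = np.hypot(np.cos(aa).sum(), np.sin(aa).sum())
    R2 = np.hypot(np.cos(bb).sum(), np.sin(bb).sum())
    R = np.hypot(np.cos(aa).sum() + np.cos(bb).sum(), np.sin(aa).sum() + np.sin(bb).sum())
    rbar = (R1 + R2) / N
    k = (2 * rbar - rbar**3) / (1 - rbar**2)
    for _ in range(100):  # Newton refinement of I1/I0 inversion
        A = special.i1e(k) / special.i0e(k)
        k -= (A - rbar) / (1 - A**2 - A / k)
    K = 1 + 3 / (8 * k)
    return K * (N - 2) * (R1 + R2 - R) / (N - R1 - R2)


class TestWatsonWilliams:
    def test_identical_samples_give_f_zero_p_one(self):
        a = np.array([10.0, 20, 30, 15, 25, 5, 12, 18, 22, 28])
        res = watson_williams(a, a.copy())
        assert res.F == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0, abs=1e-5)  # p ~ 1 - O(sqrt(F))
        assert res.R1 + res.R2 == pytest.approx(res.R, abs=1e-9)

    def test_matches_independent_oracle_on_fixed_fixture(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(-40, 60, 10)
        b = rng.uniform(10, 120, 10)
        res = watson_williams(a, b)
        assert res.F == pytest.approx(_ww_oracle(a, b), abs=1e-8)

    def test_power_against_orthogonal_von_mises_means(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            a = np.rad2deg(sps.vonmises.rvs(5, loc=0, size=200, random_state=rng))
            b = np.rad2deg(sps.vonmises.rvs(5, loc=np.pi / 2, size=200, random_state=rng))
            if watson_williams(a, b).p < 0.001:
                hits += 1
        assert hits / n_rep >= 0.99

    def test_invariance_under_common_rotation(self):
        rng = np.random.default_rng(12)
        a = rng.normal(20, 30, 40)
        b = rng.normal(70, 30, 40)
        r0 = watson_williams(a, b)
        r1 = watson_williams(a + 123.4, b + 123.4)
        assert r1.F == pytest.approx(r0.F, rel=1e-9)

    def test_group_below_min_n_is_rejected(self):
        with pytest.raises(InsufficientDataError):
            watson_williams([1.0] * 5, [2.0] * 20)

    def test_resultant_bounds(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(0, 360, 17)
        assert 0 <= resultant_length(a) <= 17


class TestAngleDistribution:
    def test_all_forward_angles_fall_in_forward_sector(self):
        pct = angle_distribution(np.zeros(10))
        assert pct[0] == 100.0

    def test_uniform_angles_spread_evenly(self):
        pct = angle_distribution(np.arange(360.0))
        np.testing.assert_allclose(pct, 12.5)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(14)
        pct = angle_distribution(rng.uniform(-180, 180, 333))
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_input_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            angle_distribution([])


class TestBuildReport:
    def test_injected_group_effect_is_flagged(self):
        rng = np.random.default_rng(15)
        table = make_table(
            lambda g, r: r.normal(25 + 5 * g, 8, 4), n_per_group=120, rng=rng
        )
        report = build_report(table)
        assert report.anovas["ddef"].effects["success"].p < 0.01
        fam = report.comparisons["ddef"]
        assert any(t.p_adjusted < 0.05 for t in fam)
        assert report.n_attacks == 240

    def test_null_cohort_rarely_rejects_the_ddef_family(self):
        rng = np.random.default_rng(16)
        clean = 0
        n_rep = 120
        for _ in range(n_rep):
            table = make_table(lambda g, r: r.normal(25, 8, 4), n_per_group=40, rng=rng)
            report = build_report(table)
            if not any(t.p_adjusted < 0.05 for t in report.comparisons["ddef"]):
                clean += 1
        assert clean / n_rep >= 0.93

    def test_report_schema_is_complete(self):
        rng = np.random.default_rng(17)
        table = make_table(lambda g, r: r.normal(25, 8, 4), n_per_group=30, rng=rng)
        report = build_report(table)
        payload = report.to_dict()
        assert set(payload["anovas"]) == {"ddef", "L", "V"}
        assert {t.label for t in report.comparisons["ddef"]} == {
            "ddef pass 1", "ddef pass 2", "ddef pass 3", "ddef pass 4", "ddef mean", "ddef max"
        }
        assert len(report.circular) == 4
        assert len(payload["angle_distributions"]) == 8
        assert "Watson-Williams" in report.render_text()
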