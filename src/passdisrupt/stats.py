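"""Statistical comparison of successful and unsuccessful attacks.

The battery mirrors a classic sports-science analysis plan: a 2 x 4
mixed-design ANOVA per dependent variable (between factor: attack success;
within factor: pass index 1-4, counting back from the final pass) with
Mauchly's sphericity test and the Greenhouse-Geisser correction; independent
t-tests per pass index and for per-attack mean/max with Levene's test
choosing the pooled or Welch form and Holm's step-down correction per
variable family; Cohen's d (always pooled SD) as effect size; and a
Watson-Williams F-test for the equality of mean pass directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import special, stats as sps
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InsufficientDataError

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class EffectRow:
    df1: float
    df2: float
    ms: float
    F: float
    p: float
    partial_eta_sq: float


@dataclass
class AnovaResult:
    """2 x 4 mixed ANOVA decomposition for one dependent variable."""

    dv: str
    effects: dict[str, EffectRow]  # keys: success, sequence, interaction
    mauchly_p: float
    gg_epsilon: float
    correction_applied: bool
    n_success: int
    n_unsuccess: int

    def to_dict(self) -> dict:
        return {
            "dv": self.dv,
            "effects": {
                k: vars(v) for k, v in self.effects.items()
            },
            "mauchly_p": self.mauchly_p,
            "gg_epsilon": self.gg_epsilon,
            "correction_applied": self.correction_applied,
            "n_success": self.n_success,
            "n_unsuccess": self.n_unsuccess,
        }


@dataclass
class TTestResult:
    """Independent two-sample comparison (successful - unsuccessful)."""

    label: str
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float
    df: float
    t: float
    p: float
    cohen_d: float
    levene_p: float | None = None
    welch: bool = False
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class CircTestResult:
    """Watson-Williams F-test for equal mean directions of two angle samples."""

    label: str
    n1: int
    n2: int
    R1: float
    R2: float
    R: float
    F: float
    p: float
    kappa: float
    correction_factor: float

    def to_dict(self) -> dict:
        return dict(vars(self))


# ---------------------------------------------------------------------------
# Elementary procedures


def cohens_d(n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float) -> float:
    """Cohen's d with the pooled standard deviation."""
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("Cohen's d needs n >= 2 per group")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    diff = mean1 - mean2
    if pooled == 0:
        if diff == 0:
            return 0.0
        raise DegenerateInputError("zero pooled SD with unequal means")
    return float(diff / pooled)


def holm_correction(p_values, alpha: float = ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p values and rejection decisions."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values, np.array([], dtype=bool)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p_values, alpha=alpha, method="holm")
    return adjusted, reject


def compare_groups(
    x,
    y,
    label: str = "",
    alpha: float = ALPHA,
) -> TTestResult:
    """Independent t-test of two samples (x = successful, y = unsuccessful).

    Levene's test (mean-centred) at ``alpha`` selects the pooled or Welch
    form; Cohen's d always uses the pooled SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError(f"comparison {label!r}: each group needs n >= 2")
    levene_p = float(sps.levene(x, y, center="mean").pvalue)
    welch = levene_p < alpha
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    d = cohens_d(len(x), x.mean(), x.std(ddof=1), len(y), y.mean(), y.std(ddof=1))
    return TTestResult(
        label=label,
        n1=len(x), mean1=float(x.mean()), sd1=float(x.std(ddof=1)),
        n2=len(y), mean2=float(y.mean()), sd2=float(y.std(ddof=1)),
        df=df, t=float(res.statistic), p=float(res.pvalue),
        cohen_d=d, levene_p=levene_p, welch=welch,
    )


def compare_groups_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float, label: str = ""
) -> TTestResult:
    """Pooled-variance t-test recomputed from summary statistics alone."""
    d = cohens_d(n1, mean1, sd1, n2, mean2, sd2)
    df = n1 + n2 - 2
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    se = pooled * np.sqrt(1 / n1 + 1 / n2)
    t = (mean1 - mean2) / se
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(
        label=label, n1=n1, mean1=mean1, sd1=sd1, n2=n2, mean2=mean2, sd2=sd2,
        df=float(df), t=float(t), p=float(p), cohen_d=d,
    )


# ---------------------------------------------------------------------------
# Mixed ANOVA


def _long_format(table: pd.DataFrame, dv: str) -> pd.DataFrame:
    cols = [f"{dv}_pass{i}" for i in (1, 2, 3, 4)]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"sequence table lacks columns {missing}")
    complete = table.dropna(subset=cols + ["success"])
    long = complete.melt(
        id_vars=["attack_id", "success"],
        value_vars=cols,
        var_name="pass_index",
        value_name="value",
    )
    long["pass_index"] = long["pass_index"].str[-1].astype(int)
    return long


def mixed_anova(table: pd.DataFrame, dv: str, alpha: float = ALPHA) -> AnovaResult:
    """2 x 4 mixed-design ANOVA on complete cases of the sequence table.

    ``dv`` is a column-family prefix (``ddef``, ``L`` or ``V``); complete
    cases are attacks with all four pass measurements.  Greenhouse-Geisser
    corrected p values are used for the within and interaction effects when
    Mauchly's test is significant at ``alpha``.
    """
    long = _long_format(table, dv)
    counts = long.groupby("success")["attack_id"].nunique()
    if len(counts) < 2 or counts.min() < 2:
        raise InsufficientDataError(
            f"mixed ANOVA on {dv!r} needs >= 2 complete attacks per success group"
        )
    if np.ptp(long["value"].to_numpy()) == 0:
        # constant dv: every effect SS is 0 by definition
        n_subj = int(counts.sum())
        zero = lambda df1, df2: EffectRow(df1=df1, df2=df2, ms=0.0, F=0.0, p=1.0, partial_eta_sq=0.0)
        effects = {
            "success": zero(1.0, float(n_subj - 2)),
            "sequence": zero(3.0, float(3 * (n_subj - 2))),
            "interaction": zero(3.0, float(3 * (n_subj - 2))),
        }
        return AnovaResult(
            dv=dv, effects=effects, mauchly_p=1.0, gg_epsilon=1.0,
            correction_applied=False,
            n_success=int(counts.get(1, 0)), n_unsuccess=int(counts.get(0, 0)),
        )
    aov = pg.mixed_anova(
        long, dv="value", within="pass_index", subject="attack_id",
        between="success", correction=True,
    )
    aov = aov.set_index("Source")
    within = aov.loc["pass_index"]
    between = aov.loc["success"]
    inter = aov.loc["Interaction"]
    mauchly_p = float(within["p_spher"])
    eps = float(within["eps"])
    corrected = mauchly_p < alpha

    def row(src, use_gg: bool) -> EffectRow:
        df1, df2 = float(src["DF1"]), float(src["DF2"])
        p = float(src["p_GG_corr"]) if (use_gg and np.isfinite(src.get("p_GG_corr", np.nan))) else float(src["p_unc"])
        if use_gg:
            df1, df2 = df1 * eps, df2 * eps
        return EffectRow(
            df1=df1, df2=df2, ms=float(src["MS"]), F=float(src["F"]),
            p=p, partial_eta_sq=float(src["np2"]),
        )

    # pingouin reports the GG-corrected p for the within effect; for the
    # interaction the same epsilon applies to the F reference distribution.
    inter_row = row(inter, False)
    if corrected:
        inter_row.df1 *= eps
        inter_row.df2 *= eps
        inter_row.p = float(sps.f.sf(inter_row.F, inter_row.df1, inter_row.df2))
    effects = {
        "success": row(between, False),
        "sequence": row(within, corrected),
        "interaction": inter_row,
    }
    return AnovaResult(
        dv=dv,
        effects=effects,
        mauchly_p=mauchly_p,
        gg_epsilon=eps,
        correction_applied=corrected,
        n_success=int(counts.get(1, 0)),
        n_unsuccess=int(counts.get(0, 0)),
    )


# ---------------------------------------------------------------------------
# Circular statistics


def resultant_length(angles_deg) -> float:
    """Length of the vector sum of unit vectors at the given angles."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(np.hypot(np.cos(a).sum(), np.sin(a).sum()))


def vonmises_kappa_ml(rbar: float) -> float:
    """Maximum-likelihood concentration from the mean resultant length:
    solve I1(kappa)/I0(kappa) = rbar."""
    if rbar <= 0:
        return 0.0
    if rbar >= 1 - 1e-12:
        return 1e8

    def f(k):
        return special.i1e(k) / special.i0e(k) - rbar

    return float(brentq(f, 1e-12, 1e8, xtol=1e-12, rtol=1e-12))


def watson_williams(
    angles_a,
    angles_b,
    label: str = "",
    min_n: int = 10,
    enforce_min_n: bool = True,
) -> CircTestResult:
    """Watson-Williams F-test for equality of two mean directions.

    F = K (N-2)(R1 + R2 - R) / (N - R1 - R2) on F(1, N-2), with the
    correction factor K = 1 + 3/(8 kappa) and kappa the ML von Mises
    concentration at mean resultant (R1 + R2)/N.
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if enforce_min_n and (len(a) < min_n or len(b) < min_n):
        raise InsufficientDataError(
            f"Watson-Williams {label!r}: each group needs n >= {min_n}"
        )
    n1, n2 = len(a), len(b)
    N = n1 + n2
    R1, R2 = resultant_length(a), resultant_length(b)
    if R1 < 1e-12 or R2 < 1e-12:
        raise DegenerateInputError("a group has zero resultant (no mean direction)")
    R = resultant_length(np.concatenate([a, b]))
    rbar = (R1 + R2) / N
    kappa = vonmises_kappa_ml(rbar)
    K = 1 + 3 / (8 * kappa) if kappa > 0 else np.inf
    denom = N - R1 - R2
    F = 0.0 if denom <= 0 else float(K * (N - 2) * max(R1 + R2 - R, 0.0) / denom)
    p = float(sps.f.sf(F, 1, N - 2))
    return CircTestResult(
        label=label, n1=n1, n2=n2, R1=R1, R2=R2, R=R,
        F=F, p=p, kappa=kappa, correction_factor=float(K),
    )


def angle_distribution(angles_deg, n_sectors: int = 8) -> np.ndarray:
    """Percentage of angles per sector; sectors of width 360/n centred on
    0, 360/n, ... degrees (sector 0 = straight forward)."""
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise InsufficientDataError("empty angle set")
    width = 360.0 / n_sectors
    idx = np.floor(((a + width / 2) % 360.0) / width).astype(int)
    counts = np.bincount(idx, minlength=n_sectors).astype(float)
    return counts / counts.sum() * 100.0


# ---------------------------------------------------------------------------
# Full report


@dataclass
class StatsReport:
    """Machine-readable results of the full statistical battery."""

    n_attacks: int
    n_success: int
    n_unsuccess: int
    success_proportion: float
    descriptives: list[TTestResult]
    anovas: dict[str, AnovaResult]
    comparisons: dict[str, list[TTestResult]]
    circular: list[CircTestResult]
    angle_distributions: dict[str, list[float]]
    alpha: float = ALPHA
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_attacks": self.n_attacks,
            "n_success": self.n_success,
            "n_unsuccess": self.n_unsuccess,
            "success_proportion": self.success_proportion,
            "descriptives": [t.to_dict() for t in self.descriptives],
            "anovas": {k: v.to_dict() for k, v in self.anovas.items()},
            "comparisons": {
                k: [t.to_dict() for t in v] for k, v in self.comparisons.items()
            },
            "circular": [c.to_dict() for c in self.circular],
            "angle_distributions": self.angle_distributions,
            "alpha": self.alpha,
            "provenance": self.provenance,
        }

    def render_text(self) -> str:
        lines = [
            f"Attacks: {self.n_attacks} "
            f"(successful {self.n_success} = {100 * self.success_proportion:.1f}%, "
            f"unsuccessful {self.n_unsuccess})",
            "",
            "ANOVAs (success x pass sequence)",
            f"{'dv':<10}{'effect':<14}{'df':>12}{'MS':>12}{'F':>10}{'p':>10}{'np2':>8}",
        ]
        for dv, aov in self.anovas.items():
            for name, e in aov.effects.items():
                lines.append(
                    f"{dv:<10}{name:<14}{f'{e.df1:.2f},{e.df2:.2f}':>12}"
                    f"{e.ms:>12.2f}{e.F:>10.2f}{e.p:>10.4f}{e.partial_eta_sq:>8.3f}"
                )
        lines += ["", "Group comparisons (successful vs unsuccessful)"]
        header = (
            f"{'comparison':<22}{'N1':>6}{'M1':>8}{'SD1':>7}{'N2':>6}{'M2':>8}{'SD2':>7}"
            f"{'t':>8}{'p':>9}{'p_holm':>9}{'d':>7}"
        )
        lines.append(header)
        for fam in list(self.comparisons.values()) + [self.descriptives]:
            for t in fam:
                p_adj = f"{t.p_adjusted:.4f}" if t.p_adjusted is not None else ""
                lines.append(
                    f"{t.label:<22}{t.n1:>6}{t.mean1:>8.2f}{t.sd1:>7.2f}"
                    f"{t.n2:>6}{t.mean2:>8.2f}{t.sd2:>7.2f}"
                    f"{t.t:>8.2f}{t.p:>9.4f}{p_adj:>9}{t.cohen_d:>7.2f}"
                )
        lines += ["", "Watson-Williams tests (pass directions)"]
        for c in self.circular:
            lines.append(
                f"{c.label:<22}F(1,{c.n1 + c.n2 - 2})={c.F:.2f}  p={c.p:.4f}  kappa={c.kappa:.2f}"
            )
        return "\n".join(lines)


_DV_COLUMNS = {
    "ddef": [("ddef_pass1", "pass 1"), ("ddef_pass2", "pass 2"), ("ddef_pass3", "pass 3"),
             ("ddef_pass4", "pass 4"), ("ddef_mean", "mean"), ("ddef_max", "max")],
    "L": [("L_pass1", "pass 1"), ("L_pass2", "pass 2"), ("L_pass3", "pass 3"),
          ("L_pass4", "pass 4"), ("L_mean", "mean"), ("L_max", "max")],
    "V": [("V_pass1", "pass 1"), ("V_pass2", "pass 2"), ("V_pass3", "pass 3"),
          ("V_pass4", "pass 4"), ("V_mean", "mean"), ("V_max", "max")],
}


def build_report(
    table: pd.DataFrame,
    alpha: float = ALPHA,
    n_sectors: int = 8,
    min_circ_n: int = 10,
    provenance: dict | None = None,
) -> StatsReport:
    """Run the full battery over a sequence table.

    Holm families: one per dependent variable (the six comparisons of a
    block) plus one for the attack descriptives (duration, pass count).
    ANOVAs and circular tests that lack sufficient data are skipped.
    """
    if table.empty:
        raise InsufficientDataError("empty sequence table")
    table = table.dropna(subset=["success"]).copy()
    table["success"] = table["success"].astype(int)
    succ = table[table["success"] == 1]
    unsucc = table[table["success"] == 0]
    n_total = len(table)

    descriptives = []
    for col, lab in (("duration_s", "duration of attack"), ("n_passes", "passes of attack")):
        try:
            descriptives.append(compare_groups(succ[col], unsucc[col], label=lab, alpha=alpha))
        except InsufficientDataError:
            pass
    if descriptives:
        adj, _ = holm_correction([t.p for t in descriptives], alpha)
        for t, a in zip(descriptives, adj):
            t.p_adjusted = float(a)

    anovas = {}
    comparisons: dict[str, list[TTestResult]] = {}
    for dv, cols in _DV_COLUMNS.items():
        try:
            anovas[dv] = mixed_anova(table, dv, alpha=alpha)
        except InsufficientDataError:
            pass
        fam = []
        for col, lab in cols:
            try:
                fam.append(
                    compare_groups(succ[col], unsucc[col], label=f"{dv} {lab}", alpha=alpha)
                )
            except InsufficientDataError:
                pass
        if fam:
            adj, _ = holm_correction([t.p for t in fam], alpha)
            for t, a in zip(fam, adj):
                t.p_adjusted = float(a)
        comparisons[dv] = fam

    circular = []
    angle_distributions = {}
    for i in (1, 2, 3, 4):
        col = f"alpha_pass{i}"
        a = succ[col].dropna().to_numpy()
        b = unsucc[col].dropna().to_numpy()
        for grp, vals in (("successful", a), ("unsuccessful", b)):
            if vals.size:
                angle_distributions[f"pass{i}_{grp}"] = list(
                    angle_distribution(vals, n_sectors)
                )
        try:
            circular.append(watson_williams(a, b, label=f"angle pass {i}", min_n=min_circ_n))
        except (InsufficientDataError, DegenerateInputError):
            pass

    return StatsReport(
        n_attacks=n_total,
        n_success=len(succ),
        n_unsuccess=len(unsucc),
        success_proportion=len(succ) / n_total if n_total else float("nan"),
        descriptives=descriptives,
        anovas=anovas,
        comparisons=comparisons,
        circular=circular,
        angle_distributions=angle_distributions,
        alpha=alpha,
        provenance=provenance or {},
    )
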