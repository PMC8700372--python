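"""End-to-end orchestration: preprocess, segment, score, classify, report.

`analyze_match` turns one match (tracking + events) into the per-attack
sequence table; `analyze_cohort` does the same for a simulated cohort;
`run_full` adds persistence: every intermediate table, the machine-readable
report, a rendered text report and the two standard figures are written to
the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .danger import AttackOutcome, DangerConfig, classify_attack, danger_at_reception, outcomes_table
from .disruption import DDefResult, ddef_for_pass
from .errors import ConfigurationError, InsufficientDataError, PassDisruptError
from .features import PassFeatures, build_sequence_table, features_for_attack
from .formations import LineAssignment, assignment_table, detect_lines
from .possession import (
    Attack,
    attach_possession,
    attacks_table,
    filter_deliberate,
    last_k_passes,
    segment_possessions,
)
from .stats import StatsReport, build_report
from .tracking import (
    MatchMeta,
    TrackingSeries,
    read_events,
    read_tracking,
    resample,
    smooth_positions,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``inputs`` (list of dicts with tracking/events/meta paths)
    or ``sim`` (simulation settings) must be given.
    """

    seed: int = 0
    outdir: str | Path | None = None
    inputs: list[dict] | None = None
    sim: synthetic.SimConfig | None = None
    n_matches: int = 1
    horizon: float = 3.0
    min_duration: float = 5.0
    min_passes: int = 3
    target_hz: float = 10.0
    smooth_window: int = 7
    smooth_sigma: float = 1.0
    danger: DangerConfig = field(default_factory=DangerConfig)
    alpha: float = 0.05
    n_sectors: int = 8
    verbose: bool = False

    def __post_init__(self):
        if (self.inputs is None) == (self.sim is None):
            raise ConfigurationError("exactly one of inputs or sim must be configured")
        if self.horizon <= 0:
            raise ConfigurationError("horizon must be positive")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None, outdir=None) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        sim = payload.pop("sim", None)
        danger_cfg = payload.pop("danger", None)
        kw = dict(payload)
        if seed is not None:
            kw["seed"] = seed
        if outdir is not None:
            kw["outdir"] = outdir
        if sim is not None:
            sim.setdefault("seed", kw.get("seed", 0))
            kw["sim"] = synthetic.SimConfig(**sim)
        if danger_cfg is not None:
            kw["danger"] = DangerConfig(**danger_cfg)
        return cls(**kw)

    def content_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class MatchArtifacts:
    """Intermediate per-match results retained for inspection and tables."""

    possessions: list
    attacks: list[Attack]
    assignments: list[LineAssignment]
    ddef_results: dict[tuple[str, int], DDefResult | None]
    features: dict[tuple[str, int], PassFeatures | None]
    outcomes: dict[str, AttackOutcome]


def analyze_match(
    series: TrackingSeries,
    events: pd.DataFrame,
    seed: int = 0,
    horizon: float = 3.0,
    min_duration: float = 5.0,
    min_passes: int = 3,
    target_hz: float = 10.0,
    smooth_window: int = 7,
    smooth_sigma: float = 1.0,
    danger_config: DangerConfig | None = None,
    id_prefix: str = "m000_a",
) -> tuple[pd.DataFrame, MatchArtifacts]:
    """Sequence table for one match.

    Preprocessing (smoothing, downsampling to ``target_hz``), possession
    segmentation, the deliberate-attack filter, formation-line detection
    (out-of-possession phase, as D-Def measures the defending side), D-Def of
    the last four passes, reception danger / success classification and pass
    features.
    """
    meta = series.meta
    danger_config = danger_config or DangerConfig()
    if smooth_window > 1:
        series = smooth_positions(series, window=smooth_window, sigma=smooth_sigma)
    if 1.0 / series.dt > target_hz * (1 + 1e-9):
        series = resample(series, target_hz)

    possessions = segment_possessions(events)
    series = attach_possession(series, possessions)
    attacks = filter_deliberate(
        possessions, min_duration=min_duration, min_passes=min_passes, id_prefix=id_prefix
    )
    log.info(
        "%s: %d possessions -> %d deliberate attacks (filtered %d)",
        id_prefix, len(possessions), len(attacks), len(possessions) - len(attacks),
    )

    assignments = []
    defense_assignment: dict[str, LineAssignment] = {}
    for team in meta.teams:
        for phase in ("out_of_possession", "in_possession"):
            try:
                assignment = detect_lines(series, team, phase=phase, seed=seed)
            except (InsufficientDataError, PassDisruptError) as exc:
                log.warning("formation detection failed for %s/%s: %s", team, phase, exc)
                continue
            assignments.append(assignment)
            if phase == "out_of_possession":
                defense_assignment[team] = assignment

    ddef_results: dict[tuple[str, int], DDefResult | None] = {}
    features: dict[tuple[str, int], PassFeatures | None] = {}
    outcomes: dict[str, AttackOutcome] = {}
    kept_attacks = []
    for attack in attacks:
        defending = meta.opponent(attack.team)
        if defending not in defense_assignment:
            log.warning("no defensive line assignment for %s; attack %s skipped",
                        defending, attack.attack_id)
            continue
        kept_attacks.append(attack)
        assignment = defense_assignment[defending]
        for idx, rec in enumerate(last_k_passes(attack, 4), start=1):
            ddef_results[(attack.attack_id, idx)] = ddef_for_pass(
                series, rec, assignment, horizon=horizon
            )
        features.update(features_for_attack(attack, meta))
        samples = [
            danger_at_reception(series, rec, meta, danger_config)
            for rec in attack.possession.completed_passes
        ]
        samples = [s for s in samples if s is not None]
        if samples:
            outcomes[attack.attack_id] = classify_attack(attack, samples)

    table = build_sequence_table(kept_attacks, ddef_results, features, outcomes)
    artifacts = MatchArtifacts(
        possessions=possessions,
        attacks=kept_attacks,
        assignments=assignments,
        ddef_results=ddef_results,
        features=features,
        outcomes=outcomes,
    )
    return table, artifacts


def analyze_cohort(
    sim: synthetic.SimConfig,
    n_matches: int,
    **analyze_kw,
) -> tuple[pd.DataFrame, dict]:
    """Simulate ``n_matches`` in memory and analyse them.

    Per-match seeds are derived exactly as in ``simulate_cohort``, so the
    in-memory and file-based routes see identical matches.
    """
    seed_rng = np.random.default_rng(sim.seed)
    tables, artifacts, truths = [], [], []
    for m in range(n_matches):
        match_seed = int(seed_rng.integers(0, 2**31 - 1))
        cfg = dataclasses.replace(sim, seed=match_seed)
        series, events, truth = synthetic.simulate_match(cfg)
        table, art = analyze_match(
            series, events, seed=match_seed, id_prefix=f"m{m:03d}_a", **analyze_kw
        )
        tables.append(table)
        artifacts.append(art)
        truths.append(truth)
    table = (
        pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    )
    return table, {"artifacts": artifacts, "truths": truths}


def _ddef_table(artifacts: list[MatchArtifacts]) -> pd.DataFrame:
    rows = []
    for art in artifacts:
        for (attack_id, idx), res in sorted(art.ddef_results.items()):
            if res is None:
                continue
            rows.append(
                dict(
                    attack_id=attack_id, pass_index=idx,
                    t_pass=res.pass_ref.t_pass if res.pass_ref else np.nan,
                    PC1=res.PC1, PC2=res.PC2, PC3=res.PC3, ddef=res.ddef,
                )
            )
    return pd.DataFrame(rows, columns=["attack_id", "pass_index", "t_pass", "PC1", "PC2", "PC3", "ddef"])


def run_full(config: RunConfig) -> StatsReport:
    """Execute the whole pipeline and persist all artifacts.

    Results go to ``outdir`` (default ``results/run_<confighash>``); every
    number in the report is reproducible from the persisted intermediate
    tables.
    """
    if config.verbose:
        logging.basicConfig(level=logging.INFO)
    outdir = Path(config.outdir) if config.outdir else Path("results") / f"run_{config.content_hash()}"
    outdir.mkdir(parents=True, exist_ok=True)

    analyze_kw = dict(
        horizon=config.horizon,
        min_duration=config.min_duration,
        min_passes=config.min_passes,
        target_hz=config.target_hz,
        smooth_window=config.smooth_window,
        smooth_sigma=config.smooth_sigma,
        danger_config=config.danger,
    )
    all_artifacts: list[MatchArtifacts] = []
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.sim.seed)
        table, info = analyze_cohort(sim, config.n_matches, **analyze_kw)
        all_artifacts = info["artifacts"]
    else:
        tables = []
        for m, paths in enumerate(config.inputs):
            meta = MatchMeta.from_yaml(paths["meta"]) if "meta" in paths else MatchMeta()
            series = read_tracking(paths["tracking"], meta)
            events = read_events(paths["events"])
            t, art = analyze_match(
                series, events, seed=config.seed, id_prefix=f"m{m:03d}_a", **analyze_kw
            )
            tables.append(t)
            all_artifacts.append(art)
        table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()

    table.to_csv(outdir / "sequence_table.csv", index=False, float_format="%.6f")
    attacks_table(
        [a for art in all_artifacts for a in art.attacks]
    ).to_csv(outdir / "attacks.csv", index=False, float_format="%.6f")
    assignment_table(
        [asg for art in all_artifacts for asg in art.assignments]
    ).to_csv(outdir / "line_assignments.csv", index=False, float_format="%.6f")
    _ddef_table(all_artifacts).to_csv(outdir / "ddef.csv", index=False, float_format="%.6f")
    outcomes_table(
        [o for art in all_artifacts for o in art.outcomes.values()]
    ).to_csv(outdir / "outcomes.csv", index=False, float_format="%.6f")

    provenance = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "n_matches": len(all_artifacts),
    }
    report = build_report(
        table, alpha=config.alpha, n_sectors=config.n_sectors, provenance=provenance
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(report.render_text() + "\n")
    try:
        save_figures(report, table, outdir)
    except Exception as exc:  # figures are best-effort side outputs
        log.warning("figure rendering failed: %s", exc)
    return report


def save_figures(report: StatsReport, table: pd.DataFrame, outdir) -> None:
    """Grouped D-Def bars per pass index and a sector rose of pass angles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    fig, ax = plt.subplots(figsize=(7, 4))
    idx = np.arange(6)
    labels = ["pass 1", "pass 2", "pass 3", "pass 4", "mean", "max"]
    cols = ["ddef_pass1", "ddef_pass2", "ddef_pass3", "ddef_pass4", "ddef_mean", "ddef_max"]
    for off, (flag, name, color) in enumerate(
        [(1, "successful", "black"), (0, "unsuccessful", "tab:blue")]
    ):
        sub = table[table["success"] == flag]
        means = [sub[c].mean() for c in cols]
        errs = [sub[c].std() for c in cols]
        ax.bar(idx + 0.4 * off - 0.2, means, 0.35, yerr=errs, capsize=2, label=name, color=color)
    ax.set_xticks(idx, labels)
    ax.set_ylabel("D-Def")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "ddef_by_pass.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 4, subplot_kw={"projection": "polar"}, figsize=(13, 3.5))
    n_sectors = len(next(iter(report.angle_distributions.values()), [0] * 8))
    theta = np.deg2rad(np.arange(n_sectors) * 360.0 / n_sectors)
    width = 2 * np.pi / n_sectors
    for i, ax in enumerate(axes, start=1):
        for grp, color in (("successful", "grey"), ("unsuccessful", "tab:blue")):
            pct = report.angle_distributions.get(f"pass{i}_{grp}")
            if pct:
                ax.bar(theta, pct, width=width * 0.45, alpha=0.7, color=color, label=grp)
        ax.set_title(f"pass {i}", fontsize=9)
    axes[0].legend(fontsize=7, loc="lower left", bbox_to_anchor=(-0.4, -0.2))
    fig.tight_layout()
    fig.savefig(outdir / "angle_rose.png", dpi=120)
    plt.close(fig)
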