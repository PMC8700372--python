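# passdisrupt

Defensive-disruption analysis of passing sequences in football (soccer),
built for performance analysts and sports scientists working with
spatiotemporal tracking data.

A pass is effective when it disturbs the opponent's defensive organisation,
not merely when it travels toward goal. `passdisrupt` implements the
**D-Def** score of a pass: the change of the defending team's collective
shape between the pass moment *t* and *t* + 3 s, summarised by ten
organisation measures — the full-team centroid (C_x, C_y), the centroids of
the defensive / midfield / attacking formation lines (C_x,def … C_y,att),
the convex-hull surface area S_area and the spread S_spread (Frobenius norm
of the centred position matrix) — combined through fixed principal-component
loadings:

```
PC1 = -0.46 ΔC_x + 0.26 ΔC_y - 0.43 ΔC_x,def + 0.24 ΔC_y,def
      - 0.43 ΔC_x,mid + 0.24 ΔC_y,mid - 0.41 ΔC_x,att + 0.24 ΔC_y,att
PC2 = -0.26 ΔC_x - 0.47 ΔC_y - 0.24 ΔC_x,def - 0.43 ΔC_y,def
      - 0.25 ΔC_x,mid - 0.43 ΔC_y,mid - 0.24 ΔC_x,att - 0.40 ΔC_y,att
PC3 =  0.71 ΔS_area + 0.71 ΔS_spread

D-Def = |PC1| + |PC2| + |PC3|          (clipped to [0, 150])
```

Around the score sits a complete pipeline:

- **tracking / events** — readers and writers for delimited-text position
  (`frame,time_s,team,player_id,x,y`, 10–25 Hz) and ball-event streams,
  Gaussian smoothing, downsampling, attack-direction normalisation;
- **possession segmentation** — possessions open at a team's first
  controlled action and close at opponent gain or a stoppage; *deliberate
  attacks* last > 5 s with ≥ 3 completed passes;
- **formation lines** — k-means (k = 3) on average player depth assigns
  DEF/MID/ATT lines (e.g. 4-4-2, 4-3-3, 3-5-2);
- **danger model** — a 0–1 danger value per reception from a zone grid over
  the last 35 m in front of goal minus a deduction for goal-side defenders
  within 4 m; an attack is *successful* iff its peak danger exceeds 0;
- **pass features** — length, velocity and full-circle pass angle
  (0° = toward the opponent goal);
- **statistics** — 2 × 4 mixed ANOVA (success × pass index, with Mauchly's
  test and the Greenhouse–Geisser correction), Levene-gated independent
  t-tests with Holm correction and pooled-SD Cohen's d, Watson–Williams
  F-tests on pass angles, and sector distributions of angles;
- **synthetic data** — a seeded match generator (22 players at 10 Hz,
  anchor-pulling player motion, tagged pass/reception events, two attack
  classes with a controllable rigid-shift disruption response) providing
  ground truth for every stage.

## Worked example

```python
from passdisrupt import RunConfig, SimConfig, run_full

config = RunConfig(seed=4, sim=SimConfig(seed=4, duration_s=300.0),
                   n_matches=3, outdir="results/demo")
report = run_full(config)
print(f"attacks: {report.n_attacks}, successful: "
      f"{100 * report.success_proportion:.1f}%")
row = [t for t in report.comparisons["ddef"] if t.label == "ddef pass 2"][0]
print(f"D-Def hockey assist: {row.mean1:.1f} vs {row.mean2:.1f} "
      f"(t={row.t:.2f}, p_holm={row.p_adjusted:.4f}, d={row.cohen_d:.2f})")
```

prints

```
attacks: 21, successful: 52.4%
D-Def hockey assist: 53.0 vs 43.8 (t=0.80, p_holm=1.0000, d=0.35)
```

21 deliberate attacks were segmented from three short simulated matches,
52.4% of which reached a positive danger value. The penultimate pass
("hockey assist") of successful attacks disrupted the defense more than in
unsuccessful attacks (D-Def 53.0 vs 43.8); at this small demonstration
cohort the Holm-adjusted p stays above 0.05. `results/demo/` then contains every
intermediate table (`sequence_table.csv`, `ddef.csv`, `outcomes.csv`, …),
the machine-readable `report.json`, a rendered `report.txt` and the
standard figures.

The same pipeline runs from the shell:

```bash
passdisrupt simulate --seed 4 --n-matches 2 --out cohort/
passdisrupt run --config run.yaml --out results/run1
```

## Data availability

Professional match tracking data are proprietary; no real match data ships
with the package. The synthetic generator (`passdisrupt.synthetic`) emits
the exact file formats the readers consume, with ground truth, so every
analysis stage is testable end to end. See `docs/methods.md` for the model
and its limitations.
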