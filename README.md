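# smoltsim

Spatially explicit individual-based simulation of downstream-migrating
Atlantic salmon smolts (*Salmo salar*) over raster hydraulic fields, aimed at
fish-passage questions near hydropower intakes: given the flow a smolt
experiences, which route does it take — into the turbine intake or past the
bypass?

The package is for movement ecologists and fish-passage engineers who have
(a) a gridded horizontal layer of a CFD solution — per-cell longitudinal,
transversal and vertical velocities *u*, *v*, *w* (m/s) and turbulent kinetic
energy TKE (m²/s²) — and (b) 2-D positional fish tracks, and who want a fast,
refittable movement model rather than a full hydrodynamic–behavioural
coupling.

## The model

Observed tracks are reduced to cell-to-cell **movement steps** (cells ≈ 0.5 m)
and each step is classified against the local resultant-flow bearing
(from *u*, *v*):

* **follow-the-flow** — step heading within ±20° of the flow bearing;
* **directional deviation** — off-flow but within ±20° of the previous
  step's heading (a deterministic burst);
* **non-directional deviation** — off-flow with a fresh heading (searching).

Two binary boosted-regression-tree (BRT) models are then fitted on the cell
hydraulics (*u*, *v*, *w*, TKE):

* **Follow-the-flow model**: P(step is flow-aligned);
* **Swim-direction model**: P(fresh random heading | step not flow-aligned).

Hyperparameters (shrinkage ∈ {0.01, 0.025, 0.005, 0.0025, 0.001}, tree
complexity 1–9, number of trees by early stopping) are tuned by stratified
k-fold cross-validation on Bernoulli deviance, with AUC reported alongside.

The simulator walks each smolt cell-by-cell: a Bernoulli draw on the
follow-the-flow probability decides flow-aligned movement (heading = flow
bearing ± 20° jitter); otherwise the first off-flow step of a bout always
draws a random heading uniform outside the flow ± 20° arc, and later off-flow
steps keep or redraw the heading per the swim-direction probability. The fish
moves to the 8-neighbour cell of nearest bearing until it enters the intake
or exit-boundary region (its fate) or exhausts a step budget. A **drift-only**
baseline follows the flow (±20°) at every step.

Because the original telemetry/CFD data are available only on request, the
package ships a first-class synthetic-data generator: a parametric
channel-with-intake flow field and tracks driven by known logistic behaviour
rules, so the whole pipeline is testable against ground truth.

## Worked example

```python
import numpy as np
import smoltsim as ss

# 1. synthetic river reach: 20 × 60 cells (0.5 m), side intake downstream
scenario = ss.make_channel_field(ss.SyntheticFieldSpec(seed=1))

# 2. ground-truth cohort, then step classification
truth = ss.TruthParams()
tracks, hidden = ss.generate_truth_tracks(scenario, truth, n_fish=300,
                                          max_steps=200, seed=1)
labeled = ss.label_steps(ss.cellize_track(tracks, scenario))
data = ss.build_datasets(labeled)

# 3. fit the two behaviour models
follow = ss.fit_brt(data.follow_table,
                    ss.BRTHyperparams(learning_rate=0.05, tree_complexity=3,
                                      n_trees=400),
                    seed=1, model_kind="follow_the_flow")
swim = ss.fit_brt(data.direction_table,
                  ss.BRTHyperparams(learning_rate=0.05, tree_complexity=2,
                                    n_trees=150),
                  seed=1, model_kind="swim_direction")

# 4. simulate 4 starts × 5 replicates, behaviour vs drift-only
starts = [(4, 1), (8, 1), (12, 1), (16, 1)]
behaviour = ss.simulate_cohort(
    ss.SimConfig(start_cells=starts, replicates_per_start=5, seed=1,
                 mode="behaviour"), follow, swim, scenario)
drift = ss.simulate_cohort(
    ss.SimConfig(start_cells=starts, replicates_per_start=5, seed=1,
                 mode="drift_only"), None, None, scenario)
```

Output (printed by the steps above plus the obvious `print`s):

```
steps: 21492 {'FOLLOW': 18180, 'DIRECTIONAL': 235, 'NONDIRECTIONAL': 3077}
follow-model influence: [('v', 53.6), ('tke', 27.3), ('w', 18.0), ('u', 1.1)]
calibration slope vs truth: 0.995
behaviour fates: {'intake': 5, 'bypass': 15, 'undetermined': 0}
drift fates:     {'intake': 5, 'bypass': 15, 'undetermined': 0}
   cohort              metric      mean       sd
behaviour           sinuosity  1.252846 0.121131
behaviour heading_change_rate 27.600012 9.462481
    drift           sinuosity  1.000000 0.000000
    drift heading_change_rate  0.000000 0.000000
```

Reading this: the cohort is follow-dominated (85% of 21,492 steps), the
fitted follow-the-flow model ranks the transversal velocity *v* as the most
influential predictor — matching the generative rule, where *v* carries the
dominant slope — and its predicted probabilities are calibrated against the
hidden truth (regression slope ≈ 1). The fate table counts each simulated
smolt's route (intake vs bypass), and behaviour-mode tracks are visibly more
complex than drift (sinuosity > 1, nonzero turning rate), as observed tracks
are.

The same pipeline is available from the shell:

```sh
smoltsim synth --out-dir out/synth --seed 1
smoltsim classify --field out/synth/field.csv --metadata out/synth/metadata.json \
    --tracks out/synth/tracks.csv --out out/labeled.csv
smoltsim fit --labeled out/labeled.csv --out-dir out/fit --seed 1
smoltsim simulate --field out/synth/field.csv --metadata out/synth/metadata.json \
    --follow-model out/fit/follow_model.joblib --swim-model out/fit/swim_model.joblib \
    --seed 1 --out-prefix out/behaviour
smoltsim evaluate --tracks behaviour=out/behaviour_tracks.csv \
    --tracks drift=out/drift_tracks.csv --out-prefix out/eval
```

Real data plug in at `classify` (track CSV: `fish_id,t,x,y`) and at the field
table (`x_index,y_index,u,v,w,tke` plus a metadata JSON with cell size,
discharge and region masks).

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults, the
synthetic-data generator's design and limits, and numerical choices.
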