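# Methods

## Model overview and assumptions

`smoltsim` treats a river reach as a 2-D raster of square cells (default
0.5 m side), one horizontal layer of a CFD solution. Each wet cell carries
four hydraulic predictors: longitudinal velocity *u* (positive downstream),
transversal velocity *v* (positive right-to-left bank), vertical velocity
*w* (positive up), and turbulent kinetic energy TKE. The model is strictly
single-layer: *w* and TKE act as predictors only, and no vertical movement
is simulated — migrating smolts are assumed to hold a constant near-surface
depth (layer 2 of 10 by convention). The local "main flow direction" is the
bearing of the horizontal resultant (*u*, *v*).

Individual movement is a biased correlated random walk on the cell grid.
One loop iteration is one cell transition; swimming speed and time are not
modelled. Movement decisions depend only on the hydraulics of the occupied
cell, with no individual (hierarchical) variation between fish — each
simulated smolt uses the same two fitted probability surfaces.

### Step classification

An observed step is **FOLLOW** when its heading lies within ± `tolerance`
(default 20°) of the departure cell's flow bearing. The 20° band absorbs
the joint uncertainty of the hydraulic model and the positional estimates;
empirical step–flow angular differences on follow-dominated data are
strongly left-skewed with most mass inside it. A non-follow step is
**DIRECTIONAL** when it stays within ±tolerance of the *immediately
preceding step's* heading, else **NONDIRECTIONAL**. The reference heading
for "maintaining direction" is deliberately the previous step (not a
smoothed heading) because that is exactly what the simulator does when a
fish keeps its heading; the first step of a fish or track segment can never
be DIRECTIONAL.

Tracks are reduced to steps by mapping positions to cells, collapsing
consecutive same-cell positions, splitting segments where the track leaves
the grid, and splitting at displacements larger than `max_displacement`
(default 5 m) between consecutive transmissions — a simple stand-in outlier
guard; pass `None` to disable. Steps that skip cells between transmissions
are kept as single steps with the full displacement's heading, rather than
inventing interpolated positions.

### Behaviour models

Both behaviour probabilities are binary gradient-boosted tree ensembles
(scikit-learn `GradientBoostingClassifier`) on (*u*, *v*, *w*, TKE):

* *follow-the-flow*: fitted on every labelled step, y = FOLLOW;
* *swim-direction*: fitted on non-FOLLOW steps that have a defined previous
  heading, y = fresh random heading (NONDIRECTIONAL). Off-flow steps that
  open a segment are excluded because their NONDIRECTIONAL label is forced
  by construction, not informative about the keep-vs-redraw choice.

Tuning grid: learning rate ∈ {0.01, 0.025, 0.005, 0.0025, 0.001} × tree
complexity (max tree depth) 1–9, i.e. 45 combinations. Model selection uses
stratified k-fold cross-validation (default k = 10) on mean Bernoulli
deviance, −2·mean(y ln p + (1−y) ln(1−p)), with AUC as the secondary
discrimination statistic; ties break towards higher CV AUC then fewer
trees. This is a deliberate simplification of the bootstrapped-subset
scheme some R tooling uses for the same selection target (10 random 70%
subsets); standard k-fold is reproducible and conventional. Grouped CV by
fish is available (`fish_id` is retained) but off by default, matching the
no-hierarchy assumption.

The number of trees is not a free input: for each grid point all folds are
grown in lock-step increments of `patience` trees (default 50, cap
`max_trees` = 10,000) and growth stops once mean held-out deviance fails to
improve over a full increment, so the selected tree count has `patience`
granularity. Published tree counts for refits are accepted verbatim as
`BRTHyperparams` fixtures. The final model is refitted on all rows at the
selected configuration. Relative influence is the ensemble's split-gain
importance normalised to percent (uniform 25% per predictor in the
degenerate no-gain case).

### Simulation loop

On entering a cell the fish draws Bernoulli(p_follow):

1. **follow** — heading = flow bearing + U(−tolerance, +tolerance); any
   non-follow bout ends;
2. **first non-follow of a bout** — heading drawn uniform over [0, 360°)
   excluding the closed arc flow ± tolerance (a random direction is always
   generated at the first non-follow);
3. **later non-follow** — Bernoulli(p_random): fresh random heading on
   success, else keep the stored heading.

Whether the forced random heading re-arms per bout (a FOLLOW decision
resets it; the default) or fires only once per fish is genuinely open; both
are implemented (`SimConfig.first_random_rule`). Likewise the drift-only
baseline jitters within ±tolerance each step by default, with an
exact-resultant variant behind `drift_jitter=False`.

Movement realises a heading as the wet 8-neighbour whose centre-to-centre
bearing is circularly closest (bearings 0°, 45°, …, 315°); exact ties break
clockwise. If the nearest neighbour is dry the next-best wet neighbour is
taken — the decision log stays faithful to the draws — and a fish with no
wet neighbour terminates. A track ends when it enters the `intake` or
`exit_boundary` region (fate: intake / bypass) or exhausts `max_steps`
(default 1000; fate: undetermined).

Reproducibility: every track uses a `numpy` substream keyed on (master
seed, start row, start col, replicate), so cohorts are bit-reproducible and
invariant to start-cell ordering. Drift-only mode substitutes constant
p_follow = 1 / p_random = 0 models into the same loop, which makes a
degenerate always-follow behaviour run and a drift run consume identical
random streams (tested as exact equivalence).

For cohort simulation the two probability surfaces are precomputed once per
scenario (vectorised prediction over all active cells) and looked up per
step; this changes nothing statistically and keeps a 20-track cohort on a
20 × 60 grid under a second.

## Synthetic data: what it emulates, what it does not

`make_channel_field` builds a straight channel: dry banks on the first and
last rows; *u* follows a parabolic cross-channel profile with a floor
(u = base_speed · (0.5 + 0.5·4f(1−f)), f the cross-channel fraction) so
near-bank flow stays brisk; *v* pulls towards a side intake block on the
downstream edge with a Gaussian longitudinal envelope; *w* is small
Gaussian noise; TKE is proportional to the cross-channel shear of *u* plus
a small noise floor. Default magnitudes (base_speed 0.7 m/s, cross-flow
≤ 0.03 m/s, TKE ≲ 0.03 m²/s²) sit inside the envelope observed for smolts
in the two source rivers. The cross-flow is deliberately small relative to
*u* so flow bearings stay within a few degrees of the downstream axis —
see below.

`generate_truth_tracks` runs the simulator's decision loop with *known*
logistic behaviour rules in place of fitted models:
p = logistic(β₀ + β_u·u + β_v·v + β_w·w + β_tke·TKE (+ β_{v·tke}·v·TKE)).
Defaults give a follow-dominated cohort (mean p_follow ≈ 0.84) whose follow
probability is driven mainly by *v* (β_v = −30 against |v| ≤ 0.03) and a
swim-direction probability driven mainly by *u* — the influence ordering
reported for wild smolts. The small v×TKE interaction exercises tree depth
> 1. Ping interval is one cell transition, so classification steps align
1:1 with generated decisions.

One generator-specific rule: a drawn heading whose realised grid move would
contradict its own decision class — because 8-neighbour quantisation or a
dry-cell deflection lands the realised bearing on the wrong side of the
±tolerance boundary — is redrawn (up to 12 attempts, then accepted). The
production simulator does *not* do this; it exists so the hidden labels
remain recoverable from the emitted cell-centre positions, which is the
point of ground truth. With it, classification recovers the hidden
FOLLOW/non-FOLLOW split at ≥ 99% (residual disagreement at corner
geometries); without it, bank deflections alone would contaminate ~1–2% of
labels.

What passing tests on this generator do **not** show: realism of actual CFD
fields (no recirculation zones, no vertical structure, static flow), tag
detection error and positioning noise (positions are exact cell centres at
a fixed ping rate), behavioural responses beyond the four hydraulic
predictors, and any predation or bioenergetic process. Parameter-recovery
results demonstrate that the pipeline is statistically sound, not that the
fitted relationships transfer to other rivers.

## Evaluation

Track complexity is summarised by path length, net displacement, sinuosity
(path/net, ≥ 1, flagged undefined for closed paths), mean absolute per-step
heading change, and the fraction of visited cells entered more than once —
quantitative proxies for the visual track comparison used in field studies
(searching shows up as revisits and back-and-forth movement).
`compare_cohorts` tabulates fates and metric means/SDs across named
cohorts; `matched_simulation` replicates an observed track with matched
initial conditions (same start cell, step budget = observed step count,
default 3 replicates). No significance testing is attempted between
cohorts.

## Numerical choices

* Headings are mathematical "to" bearings, degrees counter-clockwise from
  the +u (downstream) axis in [0, 360); helpers that return meteorological
  "from" directions must be converted before refitting against their
  output. The zero vector gets heading 0 by convention, and a guard maps
  the floating-point edge `x % 360 == 360.0` back to 0.
* Probabilities are clipped to [1e-12, 1−1e-12] inside the deviance (numeric
  safety, negligible bias) and model predictions to the open interval
  (1e-9, 1−1e-9).
* AUC uses average ranks, counting ties as ½ (Mann–Whitney form).
* Absent (dry) cells are all-NaN across the four predictors; partially
  missing cells are rejected at load.
* Grid indexing is 0-based (row, col) row-major with `x_index` = col along
  +u and `y_index` = row along +v.

## Problem sizes used by the test suite and acceptance script

Synthetic cohorts use the default 20 × 60-cell channel. Parameter recovery
uses 300 fish × ≤ 200 steps (≈ 21k steps) with a fixed moderate
configuration (shrinkage 0.05, depth 3, 400 trees) for the final fit;
grid-tuning checks run the full 45-point grid on a 300-row table with small
tree caps, which exercises the search machinery without hour-scale
boosting runs. Cohort comparisons use the 4-starts × 5-replicates design.
These sizes were chosen so the full pipeline, including tuning, stays at
desk scale while every statistical property under test has enough data to
be stable across seeds.

## Known limitations

* Single horizontal layer; no depth choice, no 3-D hydraulics.
* No swimming speed or time dimension — one step is one cell, so transit
  times are not predictions.
* The BRT tuning protocol (stratified k-fold) differs from the
  bootstrapped-subset scheme of the original R tooling; selected
  hyperparameters may differ slightly on the same data.
* The heading convention of external resultant-direction helpers is not
  assumed; refits against outputs of such tools must convert explicitly.
* Fate accounting depends entirely on user-supplied `intake` and
  `exit_boundary` masks; misplaced masks silently re-label fates.
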