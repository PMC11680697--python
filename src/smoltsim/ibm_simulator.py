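"""Stochastic individual-based movement engine for migrating smolts.

Each simulated smolt occupies one raster cell at a time and moves one cell
per iteration (≈0.5 m).  On entering a cell the follow-the-flow model gives
the probability that the fish stays flow-aligned; a Bernoulli draw decides.

* **Follow**: the heading is the local resultant-flow bearing jittered
  uniformly within ±tolerance, and any non-follow bout ends.
* **First non-follow of a bout**: a random heading is always drawn —
  uniform over [0, 360) excluding the closed arc flow ± tolerance.
* **Later non-follow steps**: the swim-direction model gives the
  probability of a fresh random heading (searching); otherwise the stored
  heading is kept (directional burst).

The fish then moves to the 8-neighbour whose centre-to-centre bearing is
circularly closest to the heading (clockwise-first on ties; dry neighbours
fall through to the next-best wet one).  The loop runs until the smolt
enters the turbine-intake or exit-boundary region — its fate — or a step
budget is exhausted.  A drift-only baseline follows the flow (±tolerance)
at every step.

Reproducibility: every track draws from its own counter-based substream
keyed on (master seed, start cell, replicate), so a cohort is reproducible
and independent of the order in which tracks are run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Protocol, Sequence

import numpy as np

from .hydraulic_field import (
    FlowScenario,
    HydraulicCell,
    flow_heading_grid,
    resultant_flow,
    wrap360,
)
from .track_classification import Behaviour, circular_difference

DEFAULT_MAX_STEPS = 1000
DEFAULT_TOLERANCE_DEG = 20.0

#: 8-connected neighbourhood: (drow, dcol) → centre-to-centre bearing (deg)
NEIGHBOUR_BEARINGS: tuple[tuple[tuple[int, int], float], ...] = (
    ((0, 1), 0.0),
    ((1, 1), 45.0),
    ((1, 0), 90.0),
    ((1, -1), 135.0),
    ((0, -1), 180.0),
    ((-1, -1), 225.0),
    ((-1, 0), 270.0),
    ((-1, 1), 315.0),
)

Fate = Literal["intake", "bypass", "undetermined"]
Termination = Literal["exited", "max_steps_reached"]


class BehaviourProbabilityModel(Protocol):
    """Anything mapping a cell's hydraulics to a probability in (0, 1)."""

    def predict_prob(self, hydraulics: HydraulicCell) -> float: ...


@dataclass(frozen=True)
class ConstantProbabilityModel:
    """Degenerate behaviour model returning a fixed probability (stub/baseline)."""

    p: float

    def predict_prob(self, hydraulics: HydraulicCell) -> float:
        return self.p


@dataclass
class SmoltState:
    """Mutable per-individual state during the simulation loop."""

    cell: tuple[int, int]
    heading: float | None = None
    in_nonfollow_bout: bool = False
    steps_taken: int = 0
    trajectory: list[tuple[int, int]] = field(default_factory=list)
    behaviour_log: list[Behaviour] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trajectory:
            self.trajectory = [self.cell]


@dataclass
class SimConfig:
    """Cohort simulation settings.

    Defaults mirror the reference simulation design: a step budget of 1000
    cells per fish, ±20° flow tolerance, and five replicates from each of
    the chosen start cells.  ``first_random_rule`` controls whether the
    forced random heading at the first non-follow decision applies per
    non-follow bout (default: a FOLLOW decision re-arms it) or once per
    fish.  ``drift_jitter`` controls whether drift-only headings jitter
    within ±tolerance (default) or track the exact resultant.
    """

    start_cells: Sequence[tuple[int, int]]
    replicates_per_start: int = 5
    max_steps: int = DEFAULT_MAX_STEPS
    tolerance: float = DEFAULT_TOLERANCE_DEG
    seed: int = 0
    mode: Literal["behaviour", "drift_only"] = "behaviour"
    first_random_rule: Literal["per_bout", "per_fish"] = "per_bout"
    drift_jitter: bool = True
    scenario_id: str | None = None

    def __post_init__(self) -> None:
        if self.replicates_per_start < 1:
            raise ValueError("replicates_per_start must be >= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not 0 <= self.tolerance < 180:
            raise ValueError("tolerance must lie in [0, 180)")
        if self.mode not in ("behaviour", "drift_only"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SimulatedTrack:
    start_cell: tuple[int, int]
    cells: list[tuple[int, int]]
    behaviour_log: list[Behaviour]
    headings: list[float]
    termination: Termination
    fate: Fate
    replicate: int = 0

    @property
    def n_steps(self) -> int:
        return len(self.cells) - 1


@dataclass
class CohortResult:
    tracks: list[SimulatedTrack]
    fate_counts: dict[str, int]
    mode: str


# -- elementary draws -------------------------------------------------------


def draw_random_heading(
    flow_heading: float, tolerance: float, rng: np.random.Generator
) -> float:
    """Uniform heading over [0, 360) excluding the closed arc flow ± tolerance."""
    offset = rng.uniform(tolerance, 360.0 - tolerance)
    return wrap360(flow_heading + offset)


def _follow_heading(
    flow_hdg: float, tolerance: float, rng: np.random.Generator, jitter: bool = True
) -> float:
    if not jitter:
        return flow_hdg
    return wrap360(flow_hdg + rng.uniform(-tolerance, tolerance))


def decide_step(
    state: SmoltState,
    hydraulics: HydraulicCell,
    follow_model: BehaviourProbabilityModel,
    direction_model: BehaviourProbabilityModel,
    tolerance: float,
    rng: np.random.Generator,
    flow_hdg: float | None = None,
) -> tuple[Behaviour, float]:
    """One behavioural decision: returns the label and the new heading.

    Mutates ``state.heading`` and ``state.in_nonfollow_bout``.  Labels reuse
    the observational vocabulary: FOLLOW (flow-aligned), NONDIRECTIONAL
    (fresh random heading), DIRECTIONAL (kept heading).
    """
    if hydraulics.is_absent:
        raise ValueError("decide_step on a dry/absent cell")
    if flow_hdg is None:
        flow_hdg = resultant_flow(hydraulics.u, hydraulics.v).heading
    p_follow = follow_model.predict_prob(hydraulics)
    return _decide(state, p_follow, direction_model, hydraulics, flow_hdg, tolerance, rng)


def _decide(
    state: SmoltState,
    p_follow: float,
    direction_model,
    hydraulics,
    flow_hdg: float,
    tolerance: float,
    rng: np.random.Generator,
    p_random: float | None = None,
) -> tuple[Behaviour, float]:
    if rng.random() < p_follow:
        heading = _follow_heading(flow_hdg, tolerance, rng)
        state.in_nonfollow_bout = False
        state.heading = heading
        return Behaviour.FOLLOW, heading
    if not state.in_nonfollow_bout or state.heading is None:
        # first non-follow of a bout: a random direction is always generated
        heading = draw_random_heading(flow_hdg, tolerance, rng)
        state.in_nonfollow_bout = True
        state.heading = heading
        return Behaviour.NONDIRECTIONAL, heading
    if p_random is None:
        p_random = direction_model.predict_prob(hydraulics)
    if rng.random() < p_random:
        heading = draw_random_heading(flow_hdg, tolerance, rng)
        state.heading = heading
        return Behaviour.NONDIRECTIONAL, heading
    return Behaviour.DIRECTIONAL, float(state.heading)


def move(
    state: SmoltState, heading: float, scenario: FlowScenario
) -> tuple[int, int] | None:
    """Next cell for a heading: the wet 8-neighbour of nearest bearing.

    Ties (a heading exactly between two neighbour bearings) break towards
    the clockwise neighbour.  If the nearest neighbour is dry the next-best
    wet neighbour is taken; with no wet neighbour at all, None is returned
    and the track terminates.
    """
    r, c = state.cell
    ranked = sorted(
        NEIGHBOUR_BEARINGS,
        key=lambda nb: (
            circular_difference(nb[1], heading),
            0 if ((nb[1] - heading + 180.0) % 360.0) - 180.0 <= 0 else 1,
        ),
    )
    for (dr, dc), _bearing in ranked:
        cell = (r + dr, c + dc)
        if scenario.is_active(cell):
            return cell
    return None


# -- track and cohort loops -------------------------------------------------


def _track_rng(seed: int, start: tuple[int, int], replicate: int) -> np.random.Generator:
    # substream keyed on (seed, cell, replicate): order-independent cohorts
    return np.random.default_rng([int(seed), int(start[0]), int(start[1]), int(replicate)])


class _GridProbabilityModel:
    """Per-cell probability lookup precomputed for one scenario (fast path)."""

    def __init__(self, grid: np.ndarray):
        self.grid = grid

    @classmethod
    def from_model(
        cls, model: BehaviourProbabilityModel, scenario: FlowScenario
    ) -> "_GridProbabilityModel":
        grid = np.full(scenario.shape, np.nan)
        if isinstance(model, ConstantProbabilityModel):
            grid[scenario.active] = model.p
            return cls(grid)
        if hasattr(model, "predict_frame"):
            frame = scenario.predictor_frame()
            grid[frame["row"].to_numpy(), frame["col"].to_numpy()] = model.predict_frame(frame)
            return cls(grid)
        rows, cols = np.nonzero(scenario.active)
        for r, c in zip(rows, cols):
            grid[r, c] = model.predict_prob(scenario.hydraulics((r, c)))
        return cls(grid)


def simulate_smolt(
    config: SimConfig,
    start_cell: tuple[int, int],
    follow_model: BehaviourProbabilityModel | None,
    direction_model: BehaviourProbabilityModel | None,
    scenario: FlowScenario,
    rng: np.random.Generator,
    replicate: int = 0,
    _grids: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> SimulatedTrack:
    """Simulate one smolt from ``start_cell`` until exit or step budget.

    In ``drift_only`` mode the behaviour models are replaced by constants
    (always follow), which keeps the random-number stream identical to a
    behaviour-mode run with a degenerate p_follow = 1 model.
    """
    if not scenario.is_active(start_cell):
        raise ValueError(f"start cell {start_cell} is outside navigable water")
    if config.mode == "drift_only":
        follow_model = ConstantProbabilityModel(1.0)
        direction_model = ConstantProbabilityModel(0.0)
    if follow_model is None or direction_model is None:
        raise ValueError("behaviour mode requires both fitted models")

    if _grids is None:
        flow_grid = flow_heading_grid(scenario)
        p_follow_grid = _GridProbabilityModel.from_model(follow_model, scenario).grid
        p_random_grid = _GridProbabilityModel.from_model(direction_model, scenario).grid
    else:
        flow_grid, p_follow_grid, p_random_grid = _grids

    state = SmoltState(cell=start_cell)
    headings: list[float] = []
    termination: Termination = "max_steps_reached"
    jitter = config.drift_jitter if config.mode == "drift_only" else True
    ever_nonfollow = False

    for _ in range(config.max_steps):
        r, c = state.cell
        flow_hdg = float(flow_grid[r, c])
        if jitter:
            label, heading = _decide(
                state,
                float(p_follow_grid[r, c]),
                None,
                None,
                flow_hdg,
                config.tolerance,
                rng,
                p_random=float(p_random_grid[r, c]),
            )
        else:  # exact-resultant drift variant
            label, heading = Behaviour.FOLLOW, flow_hdg
            state.heading = heading
        if label is not Behaviour.FOLLOW:
            ever_nonfollow = True
        if config.first_random_rule == "per_fish" and ever_nonfollow:
            # the forced-random rule fires once per fish: a follow decision
            # does not re-arm it, so later bouts consult the swim-direction model
            state.in_nonfollow_bout = True
        next_cell = move(state, heading, scenario)
        if next_cell is None:
            break
        state.cell = next_cell
        state.trajectory.append(next_cell)
        state.behaviour_log.append(label)
        state.steps_taken += 1
        headings.append(heading)
        if scenario.in_region(next_cell, "intake") or scenario.in_region(
            next_cell, "exit_boundary"
        ):
            termination = "exited"
            break

    track = SimulatedTrack(
        start_cell=start_cell,
        cells=state.trajectory,
        behaviour_log=state.behaviour_log,
        headings=headings,
        termination=termination,
        fate="undetermined",
        replicate=replicate,
    )
    track.fate = classify_fate(track, scenario)
    return track


def classify_fate(track: SimulatedTrack, scenario: FlowScenario) -> Fate:
    """Fate of a terminated track: intake, bypass, or undetermined."""
    final = track.cells[-1]
    if scenario.in_region(final, "intake"):
        return "intake"
    if scenario.in_region(final, "exit_boundary"):
        return "bypass"
    return "undetermined"


def simulate_cohort(
    config: SimConfig,
    follow_model: BehaviourProbabilityModel | None,
    direction_model: BehaviourProbabilityModel | None,
    scenario: FlowScenario,
) -> CohortResult:
    """Simulate ``len(start_cells) × replicates_per_start`` smolts.

    Each track gets its own RNG substream keyed on (seed, start cell,
    replicate), so the cohort is reproducible and invariant to the order of
    the start cells.
    """
    fm = ConstantProbabilityModel(1.0) if config.mode == "drift_only" else follow_model
    dm = ConstantProbabilityModel(0.0) if config.mode == "drift_only" else direction_model
    if fm is None or dm is None:
        raise ValueError("behaviour mode requires both fitted models")
    grids = (
        flow_heading_grid(scenario),
        _GridProbabilityModel.from_model(fm, scenario).grid,
        _GridProbabilityModel.from_model(dm, scenario).grid,
    )
    tracks = []
    for start in config.start_cells:
        for rep in range(config.replicates_per_start):
            rng = _track_rng(config.seed, start, rep)
            tracks.append(
                simulate_smolt(
                    config, tuple(start), fm, dm, scenario, rng, replicate=rep, _grids=grids
                )
            )
    counts = {"intake": 0, "bypass": 0, "undetermined": 0}
    for t in tracks:
        counts[t.fate] += 1
    return CohortResult(tracks=tracks, fate_counts=counts, mode=config.mode)
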