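"""Parametric hydraulic fields and ground-truth smolt tracks.

The study data behind the fitted behaviour models (telemetry positions and
CFD rasters for two Norwegian rivers) are not redistributable, so this
module emulates both halves at desk scale:

* :func:`make_channel_field` builds a straight channel with a parabolic
  downstream-velocity profile, dry banks, a side turbine intake that pulls
  a smooth transversal component towards itself, a weak random vertical
  component, and TKE proportional to the local cross-channel shear — the
  qualitative anatomy of a river reach in front of a hydropower intake.

* :func:`generate_truth_tracks` runs the movement engine with *known*
  logistic behaviour rules (``p_follow`` and ``p_random`` as logistic
  functions of u, v, w, TKE, optionally with a v×TKE interaction) and emits
  positional tracks plus the hidden per-step decisions and probabilities,
  so classification and model fitting can be checked against ground truth.

Default magnitudes are chosen to sit inside the envelope of the two source
rivers (downstream velocities a few tenths of a m/s to ≈1 m/s, TKE of order
10⁻² m²/s²) while keeping the cross-flow small enough that flow bearings
stay close to the grid axes; see the methods note for what this does and
does not exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .hydraulic_field import FlowScenario, HydraulicCell, flow_heading_grid, wrap360
from .ibm_simulator import Behaviour, SmoltState, draw_random_heading, move
from .track_classification import DEFAULT_TOLERANCE_DEG, circular_difference


@dataclass
class SyntheticFieldSpec:
    """Parameters of the parametric channel-with-intake flow field.

    ``base_speed`` scales the parabolic downstream profile;
    ``cross_flow_amplitude`` bounds the transversal pull towards the intake
    (kept small relative to ``base_speed`` so flow bearings stay within a
    few degrees of downstream); ``intake_position`` is a (row_start,
    row_stop) half-open range and a column, defaulting to a block on the
    right-bank side of the downstream edge; ``intake_attraction`` scales
    the pull (0 disables it, making the field purely longitudinal).
    """

    n_rows: int = 20
    n_cols: int = 60
    base_speed: float = 0.7
    cross_flow_amplitude: float = 0.03
    intake_position: tuple[tuple[int, int], int] | None = None
    intake_attraction: float = 1.0
    tke_scale: float = 0.03
    w_amplitude: float = 0.02
    cell_size: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 5 or self.n_cols < 5:
            raise ValueError("field must be at least 5×5 cells")
        if not self.base_speed > 0:
            raise ValueError("base_speed must be positive")
        if self.tke_scale < 0:
            raise ValueError("tke_scale must be non-negative")
        if self.intake_position is None:
            self.intake_position = ((1, max(2, self.n_rows // 3)), self.n_cols - 1)
        (r0, r1), col = self.intake_position
        if not (0 <= r0 < r1 <= self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"intake_position {self.intake_position} outside grid")


@dataclass
class TruthCoefficients:
    """Logistic-link coefficients for one behaviour probability."""

    intercept: float
    u: float
    v: float
    w: float
    tke: float
    v_tke: float = 0.0  # optional v×TKE interaction

    def linear(self, u: float, v: float, w: float, tke: float):
        return (
            self.intercept
            + self.u * u
            + self.v * v
            + self.w * w
            + self.tke * tke
            + self.v_tke * v * tke
        )


@dataclass
class TruthParams:
    """Known generative behaviour rules used in place of fitted models.

    Defaults give a follow-dominated cohort (mean p_follow ≈ 0.85) whose
    follow probability is driven mainly by the transversal velocity v, and
    a swim-direction probability driven mainly by u — mirroring the
    influence ordering reported for wild smolts.
    """

    follow_coefficients: TruthCoefficients = field(
        default_factory=lambda: TruthCoefficients(
            intercept=0.8, u=1.5, v=-30.0, w=1.0, tke=-6.0, v_tke=50.0
        )
    )
    random_coefficients: TruthCoefficients = field(
        default_factory=lambda: TruthCoefficients(
            intercept=-1.2, u=3.0, v=4.0, w=1.0, tke=10.0
        )
    )
    tolerance: float = DEFAULT_TOLERANCE_DEG


def _logistic(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def truth_probability(
    truth: TruthParams, hydraulics: HydraulicCell | Sequence[float]
) -> tuple[float, float]:
    """(p_follow, p_random) under the known logistic rules for one cell."""
    u, v, w, tke = (float(x) for x in hydraulics)
    return (
        _logistic(truth.follow_coefficients.linear(u, v, w, tke)),
        _logistic(truth.random_coefficients.linear(u, v, w, tke)),
    )


class LogisticTruthModel:
    """Adapter exposing one truth rule through the behaviour-model protocol."""

    def __init__(self, coefficients: TruthCoefficients):
        self.coefficients = coefficients

    def predict_prob(self, hydraulics) -> float:
        u, v, w, tke = (float(x) for x in hydraulics)
        return _logistic(self.coefficients.linear(u, v, w, tke))

    def predict_frame(self, table: pd.DataFrame) -> np.ndarray:
        c = self.coefficients
        z = (
            c.intercept
            + c.u * table["u"].to_numpy()
            + c.v * table["v"].to_numpy()
            + c.w * table["w"].to_numpy()
            + c.tke * table["tke"].to_numpy()
            + c.v_tke * table["v"].to_numpy() * table["tke"].to_numpy()
        )
        return 1.0 / (1.0 + np.exp(-z))


def make_channel_field(spec: SyntheticFieldSpec) -> FlowScenario:
    """Build the parametric channel scenario described in the module docstring.

    The first and last rows are dry banks.  The ``intake`` region sits at
    ``intake_position``; the ``exit_boundary`` region is the remainder of
    the downstream edge.  Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_rows, n_cols = spec.n_rows, spec.n_cols
    rows = np.arange(n_rows, dtype=float)
    f = rows / (n_rows - 1)  # 0 at right bank, 1 at left bank
    # parabolic cross-channel profile with a floor so near-bank flow stays brisk
    profile = 0.5 + 0.5 * (4.0 * f * (1.0 - f))
    u = np.tile((spec.base_speed * profile)[:, None], (1, n_cols))

    (r0, r1), intake_col = spec.intake_position
    intake_mid = 0.5 * (r0 + r1 - 1)
    col_idx = np.arange(n_cols, dtype=float)
    # transversal pull towards the intake rows, strongest near the intake column
    proximity = np.exp(-0.5 * ((col_idx - intake_col) / (0.25 * n_cols)) ** 2)
    toward = np.sign(intake_mid - rows)  # +v points towards higher rows
    v = (
        spec.intake_attraction
        * spec.cross_flow_amplitude
        * toward[:, None]
        * proximity[None, :]
    )
    w = spec.w_amplitude * rng.standard_normal((n_rows, n_cols))
    # TKE from the cross-channel shear of u, plus a small noise floor
    shear = np.abs(np.gradient(u, axis=0))
    max_shear = shear.max() if shear.max() > 0 else 1.0
    tke = spec.tke_scale * (shear / max_shear) + 0.1 * spec.tke_scale * rng.random(
        (n_rows, n_cols)
    )

    absent = np.zeros((n_rows, n_cols), dtype=bool)
    absent[0, :] = absent[-1, :] = True  # dry banks
    for a in (u, v, w, tke):
        a[absent] = np.nan

    intake = np.zeros((n_rows, n_cols), dtype=bool)
    intake[r0:r1, intake_col] = True
    intake &= ~absent
    exit_boundary = np.zeros((n_rows, n_cols), dtype=bool)
    exit_boundary[:, n_cols - 1] = True
    exit_boundary &= ~absent & ~intake

    return FlowScenario(
        u=u,
        v=v,
        w=w,
        tke=tke,
        cell_size=spec.cell_size,
        discharge_q=None,
        bypass_fraction=None,
        layer_index=2,
        regions={"intake": intake, "exit_boundary": exit_boundary},
    )


def default_start_cells(
    scenario: FlowScenario, n: int = 4, col: int = 1
) -> list[tuple[int, int]]:
    """Start cells spread across the channel near the upstream edge."""
    active_rows = [r for r in range(scenario.shape[0]) if scenario.is_active((r, col))]
    if not active_rows:
        raise ValueError(f"no active cells in column {col}")
    picks = np.linspace(0, len(active_rows) - 1, n).round().astype(int)
    return [(active_rows[i], col) for i in picks]


def generate_truth_tracks(
    scenario: FlowScenario,
    truth: TruthParams,
    n_fish: int = 20,
    start_cells: Sequence[tuple[int, int]] | None = None,
    max_steps: int = 200,
    seed: int = 0,
    ping_interval: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate fish under the truth rules; emit tracks and hidden labels.

    Returns ``(tracks, truth_steps)``: ``tracks`` has one row per position
    (fish_id, t, x, y at cell centres, one cell transition per ping);
    ``truth_steps`` has one row per step with the hidden decision label and
    the true (p_follow, p_random) at the departure cell.  Together they let
    the classification → fitting pipeline be checked against ground truth.

    The behavioural decisions follow the simulator's loop exactly
    (Bernoulli(p_follow), forced random heading at the first non-follow of
    a bout, Bernoulli(p_random) thereafter).  Heading *realisation* adds an
    emission-consistency rule specific to this generator: a drawn heading
    whose realised grid move would contradict its own decision class —
    because the 8-neighbour quantisation or a dry-cell deflection lands the
    step on the wrong side of the ±tolerance boundary — is redrawn (a few
    attempts, then accepted as-is).  This keeps the hidden labels
    recoverable from the emitted cell-centre positions, which is the point
    of the ground truth; residual disagreement is confined to rare corner
    geometries.
    """
    if start_cells is None:
        start_cells = default_start_cells(scenario)
    follow_truth = LogisticTruthModel(truth.follow_coefficients)
    random_truth = LogisticTruthModel(truth.random_coefficients)
    flow_grid = flow_heading_grid(scenario)
    frame = scenario.predictor_frame()
    p_follow_grid = np.full(scenario.shape, np.nan)
    p_random_grid = np.full(scenario.shape, np.nan)
    rows_idx = frame["row"].to_numpy()
    cols_idx = frame["col"].to_numpy()
    p_follow_grid[rows_idx, cols_idx] = follow_truth.predict_frame(frame)
    p_random_grid[rows_idx, cols_idx] = random_truth.predict_frame(frame)

    def realised_bearing(frm: tuple[int, int], to: tuple[int, int]) -> float:
        return wrap360(float(np.degrees(np.arctan2(to[0] - frm[0], to[1] - frm[1]))))

    def consistent_move(state, draw, want_follow, flow_hdg, rng, max_redraws=12):
        """Draw a heading, redrawing while the realised move contradicts its class."""
        heading, nxt = None, None
        for _ in range(max_redraws):
            heading = draw(rng)
            nxt = move(state, heading, scenario)
            if nxt is None:
                return heading, None
            realised = realised_bearing(state.cell, nxt)
            aligned = circular_difference(realised, flow_hdg) <= truth.tolerance
            if aligned == want_follow:
                break
        return heading, nxt

    track_rows = []
    step_rows = []
    tol = truth.tolerance
    for i in range(n_fish):
        fish_id = f"synthetic_{i:03d}"
        start = tuple(start_cells[i % len(start_cells)])
        rng = np.random.default_rng([int(seed), i])
        state = SmoltState(cell=start)
        x, y = scenario.cell_centre(start)
        track_rows.append((fish_id, 0.0, x, y))
        for step_i in range(max_steps):
            r, c = state.cell
            flow_hdg = float(flow_grid[r, c])
            if rng.random() < float(p_follow_grid[r, c]):
                label = Behaviour.FOLLOW
                state.in_nonfollow_bout = False
                heading, nxt = consistent_move(
                    state,
                    lambda g: wrap360(flow_hdg + g.uniform(-tol, tol)),
                    True,
                    flow_hdg,
                    rng,
                )
                state.heading = heading
            elif not state.in_nonfollow_bout or state.heading is None or (
                rng.random() < float(p_random_grid[r, c])
            ):
                # forced random at the first non-follow of a bout, else a
                # p_random success: either way a fresh random heading
                label = Behaviour.NONDIRECTIONAL
                state.in_nonfollow_bout = True
                heading, nxt = consistent_move(
                    state,
                    lambda g: draw_random_heading(flow_hdg, tol, g),
                    False,
                    flow_hdg,
                    rng,
                )
                state.heading = heading
            else:
                label = Behaviour.DIRECTIONAL
                heading = float(state.heading)
                nxt = move(state, heading, scenario)
            if nxt is None:
                break
            step_rows.append(
                {
                    "fish_id": fish_id,
                    "step": step_i,
                    "from_row": r,
                    "from_col": c,
                    "to_row": nxt[0],
                    "to_col": nxt[1],
                    "decision": label.value,
                    "heading": heading,
                    "p_follow": float(p_follow_grid[r, c]),
                    "p_random": float(p_random_grid[r, c]),
                }
            )
            state.cell = nxt
            x, y = scenario.cell_centre(nxt)
            track_rows.append((fish_id, (step_i + 1) * ping_interval, x, y))
            if scenario.in_region(nxt, "intake") or scenario.in_region(nxt, "exit_boundary"):
                break
    tracks = pd.DataFrame(track_rows, columns=["fish_id", "t", "x", "y"])
    truth_steps = pd.DataFrame(step_rows)
    return tracks, truth_steps
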