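"""Classify observed track steps into hydraulics-driven swimming behaviours.

An observed 2-D track (positions at successive tag transmissions) is reduced
to *movement steps*: transitions between distinct raster cells.  Each step is
assigned one of three behaviours by comparing its realised heading with the
local resultant-flow bearing:

FOLLOW
    the step heading lies within ±tolerance (default 20°) of the flow
    bearing at the departure cell — flow-aligned swimming or drift;
DIRECTIONAL
    a non-flow-aligned step that maintains the previous step's heading
    within ±tolerance — a deterministic burst away from the flow;
NONDIRECTIONAL
    a non-flow-aligned step with a fresh heading — searching behaviour.

The ±20° default absorbs the joint uncertainty of the hydraulic model and
the positional/directional observations.  From the labelled steps two binary
training tables are built: the *follow-the-flow* table (all steps,
y = FOLLOW) and the *swim-direction* table (non-FOLLOW steps with a defined
previous heading, y = fresh random heading).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .hydraulic_field import FlowScenario, HydraulicCell, flow_heading, wrap360

DEFAULT_TOLERANCE_DEG = 20.0
DEFAULT_MAX_DISPLACEMENT_M = 5.0

TRACK_COLUMNS = ("fish_id", "t", "x", "y")


class Behaviour(str, enum.Enum):
    FOLLOW = "FOLLOW"
    DIRECTIONAL = "DIRECTIONAL"
    NONDIRECTIONAL = "NONDIRECTIONAL"

    def __str__(self) -> str:  # plain value in CSV output
        return self.value


class TrackPoint(NamedTuple):
    fish_id: str
    t: float
    x: float
    y: float


@dataclass(frozen=True)
class MovementStep:
    """One cell-to-cell transition of one fish.

    ``prev_step_heading`` is None for the first step of a fish or of a track
    segment (segments are split where the track leaves the grid or jumps
    implausibly far between transmissions).
    """

    fish_id: str
    from_cell: tuple[int, int]
    to_cell: tuple[int, int]
    step_heading: float
    flow_heading: float
    prev_step_heading: float | None
    hydraulics: HydraulicCell


@dataclass(frozen=True)
class LabeledStep:
    step: MovementStep
    behaviour: Behaviour


@dataclass
class BehaviorDataset:
    """The two binary training tables derived from labelled steps.

    ``follow_table``: one row per labelled step, columns u, v, w, tke,
    ``y_follow`` (1 = FOLLOW).  ``direction_table``: one row per non-FOLLOW
    step with a defined previous heading, ``y_random`` (1 = NONDIRECTIONAL).
    """

    follow_table: pd.DataFrame
    direction_table: pd.DataFrame


def circular_difference(a: float, b: float) -> float:
    """Smallest absolute angle between two bearings, in [0, 180] degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def step_heading(from_xy: tuple[float, float], to_xy: tuple[float, float]) -> float:
    """Bearing of the displacement from one point to another, in [0, 360)."""
    dx, dy = to_xy[0] - from_xy[0], to_xy[1] - from_xy[1]
    return wrap360(float(np.degrees(np.arctan2(dy, dx))))


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a track CSV with columns fish_id, t (s), x (m), y (m)."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table lacks columns: {missing}")
    return df


def _as_frame(points) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        return points
    return pd.DataFrame(points, columns=list(TRACK_COLUMNS))


def cellize_track(
    points: pd.DataFrame | Sequence[TrackPoint],
    scenario: FlowScenario,
    max_displacement: float | None = DEFAULT_MAX_DISPLACEMENT_M,
) -> list[MovementStep]:
    """Reduce positional tracks to cell-to-cell movement steps.

    Consecutive positions in the same cell are collapsed; each emitted step
    connects distinct cells and its heading is the cell-centre to cell-centre
    bearing.  Positions outside the grid (or in dry cells) split the track
    into independent segments, as do displacements larger than
    ``max_displacement`` metres between consecutive transmissions (a simple
    outlier guard; pass None to disable).  A track entirely outside the grid
    yields an empty list.
    """
    df = _as_frame(points)
    steps: list[MovementStep] = []
    for fish_id, g in df.groupby("fish_id", sort=False):
        g = g.sort_values("t", kind="stable")
        t = g["t"].to_numpy(dtype=float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"timestamps not strictly increasing for fish {fish_id!r}")
        xs = g["x"].to_numpy(dtype=float)
        ys = g["y"].to_numpy(dtype=float)
        if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))):
            raise ValueError(f"non-finite coordinates for fish {fish_id!r}")

        # split into segments at grid exits and implausible jumps
        segment: list[tuple[int, int]] = []
        prev_xy: tuple[float, float] | None = None
        prev_heading: float | None = None

        def flush() -> None:
            nonlocal segment, prev_heading
            segment = []
            prev_heading = None

        for x, y in zip(xs, ys):
            cell = scenario.point_to_cell(x, y)
            jump = (
                max_displacement is not None
                and prev_xy is not None
                and float(np.hypot(x - prev_xy[0], y - prev_xy[1])) > max_displacement
            )
            prev_xy = (x, y)
            if cell is None or jump:
                flush()
                if cell is not None:  # a jump starts a fresh segment at this cell
                    segment = [cell]
                continue
            if segment and cell == segment[-1]:
                continue  # collapse same-cell positions
            if segment:
                frm = segment[-1]
                heading = step_heading(scenario.cell_centre(frm), scenario.cell_centre(cell))
                steps.append(
                    MovementStep(
                        fish_id=str(fish_id),
                        from_cell=frm,
                        to_cell=cell,
                        step_heading=heading,
                        flow_heading=flow_heading(scenario, frm),
                        prev_step_heading=prev_heading,
                        hydraulics=scenario.hydraulics(frm),
                    )
                )
                prev_heading = heading
            segment.append(cell)
    return steps


def label_steps(
    steps: Sequence[MovementStep], tolerance: float = DEFAULT_TOLERANCE_DEG
) -> list[LabeledStep]:
    """Assign FOLLOW / DIRECTIONAL / NONDIRECTIONAL to each step.

    FOLLOW iff the step heading is within ±tolerance of the departure cell's
    flow bearing; otherwise DIRECTIONAL iff a previous step exists and the
    heading stays within ±tolerance of it, else NONDIRECTIONAL.  The first
    step of a fish or segment can therefore never be DIRECTIONAL.
    """
    labeled = []
    for s in steps:
        if circular_difference(s.step_heading, s.flow_heading) <= tolerance:
            b = Behaviour.FOLLOW
        elif (
            s.prev_step_heading is not None
            and circular_difference(s.step_heading, s.prev_step_heading) <= tolerance
        ):
            b = Behaviour.DIRECTIONAL
        else:
            b = Behaviour.NONDIRECTIONAL
        labeled.append(LabeledStep(step=s, behaviour=b))
    return labeled


def build_datasets(labeled: Sequence[LabeledStep]) -> BehaviorDataset:
    """Build the follow-the-flow and swim-direction binary training tables."""
    follow_rows = []
    direction_rows = []
    for ls in labeled:
        h = ls.step.hydraulics
        follow_rows.append((h.u, h.v, h.w, h.tke, int(ls.behaviour is Behaviour.FOLLOW)))
        if ls.behaviour is not Behaviour.FOLLOW and ls.step.prev_step_heading is not None:
            direction_rows.append(
                (h.u, h.v, h.w, h.tke, int(ls.behaviour is Behaviour.NONDIRECTIONAL))
            )
    follow = pd.DataFrame(follow_rows, columns=["u", "v", "w", "tke", "y_follow"])
    direction = pd.DataFrame(direction_rows, columns=["u", "v", "w", "tke", "y_random"])
    return BehaviorDataset(follow_table=follow, direction_table=direction)


def labeled_steps_frame(labeled: Sequence[LabeledStep]) -> pd.DataFrame:
    """Labelled steps as a flat table (the `classify` CLI output format)."""
    rows = []
    for ls in labeled:
        s = ls.step
        rows.append(
            {
                "fish_id": s.fish_id,
                "from_row": s.from_cell[0],
                "from_col": s.from_cell[1],
                "to_row": s.to_cell[0],
                "to_col": s.to_cell[1],
                "step_heading": s.step_heading,
                "flow_heading": s.flow_heading,
                "prev_step_heading": (
                    np.nan if s.prev_step_heading is None else s.prev_step_heading
                ),
                "u": s.hydraulics.u,
                "v": s.hydraulics.v,
                "w": s.hydraulics.w,
                "tke": s.hydraulics.tke,
                "behaviour": ls.behaviour.value,
            }
        )
    return pd.DataFrame(rows)


def datasets_from_frame(frame: pd.DataFrame) -> BehaviorDataset:
    """Rebuild the two training tables from a labelled-step table on disk."""
    follow = frame[["u", "v", "w", "tke"]].copy()
    follow["y_follow"] = (frame["behaviour"] == Behaviour.FOLLOW.value).astype(int)
    nonfollow = frame[
        (frame["behaviour"] != Behaviour.FOLLOW.value) & frame["prev_step_heading"].notna()
    ]
    direction = nonfollow[["u", "v", "w", "tke"]].copy()
    direction["y_random"] = (
        nonfollow["behaviour"] == Behaviour.NONDIRECTIONAL.value
    ).astype(int)
    return BehaviorDataset(
        follow_table=follow.reset_index(drop=True),
        direction_table=direction.reset_index(drop=True),
    )
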