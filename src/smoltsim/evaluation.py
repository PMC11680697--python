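"""Cohort evaluation: track-complexity metrics, fate tables, matched replication.

The behaviour-model simulator is judged against a drift-only baseline the
same way the source study judged it: do behaviour-mode tracks show the
extra complexity (turning, revisiting, sinuosity) seen in observed tracks,
and how do the cohort fates (turbine intake versus bypass) compare?  Since
visual track comparison does not scale, the comparison here is metric-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hydraulic_field import FlowScenario
from .ibm_simulator import (
    BehaviourProbabilityModel,
    CohortResult,
    SimConfig,
    SimulatedTrack,
    _track_rng,
    simulate_smolt,
)
from .track_classification import cellize_track, step_heading


@dataclass(frozen=True)
class TrackMetrics:
    """Shape summary of one track.

    ``sinuosity`` is path length over net displacement (≥ 1); it is NaN and
    ``degenerate`` is True for closed paths (zero net displacement).
    ``heading_change_rate`` is the mean absolute per-step heading change in
    degrees; ``revisit_fraction`` the share of distinct visited cells
    entered more than once.
    """

    n_steps: int
    path_length: float
    net_displacement: float
    sinuosity: float
    heading_change_rate: float
    revisit_fraction: float
    degenerate: bool


@dataclass
class FateComparison:
    """Per-mode fate counts/proportions plus per-mode metric summaries."""

    fate_table: pd.DataFrame
    metric_summary: pd.DataFrame


def _circular_change(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def track_metrics(
    cells: Sequence[tuple[int, int]], cell_size: float = 0.5
) -> TrackMetrics:
    """Compute :class:`TrackMetrics` for a cell sequence."""
    if len(cells) < 2:
        raise ValueError("track metrics require at least 2 cells")
    pts = np.asarray([((c + 0.5) * cell_size, (r + 0.5) * cell_size) for r, c in cells])
    seg = np.diff(pts, axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    path_length = float(lengths.sum())
    net = float(np.hypot(*(pts[-1] - pts[0])))
    degenerate = net == 0.0
    sinuosity = float("nan") if degenerate else path_length / net
    headings = [step_heading(tuple(a), tuple(b)) for a, b in zip(pts[:-1], pts[1:])]
    if len(headings) > 1:
        hcr = float(np.mean([_circular_change(a, b) for a, b in zip(headings, headings[1:])]))
    else:
        hcr = 0.0
    visits = pd.Series([tuple(c) for c in cells]).value_counts()
    revisit = float((visits > 1).sum() / len(visits))
    return TrackMetrics(
        n_steps=len(cells) - 1,
        path_length=path_length,
        net_displacement=net,
        sinuosity=sinuosity,
        heading_change_rate=hcr,
        revisit_fraction=revisit,
        degenerate=degenerate,
    )


def _metrics_frame(tracks: Sequence[SimulatedTrack], cell_size: float) -> pd.DataFrame:
    rows = []
    for t in tracks:
        if len(t.cells) < 2:
            continue
        m = track_metrics(t.cells, cell_size)
        rows.append(
            {
                "n_steps": m.n_steps,
                "path_length": m.path_length,
                "net_displacement": m.net_displacement,
                "sinuosity": m.sinuosity,
                "heading_change_rate": m.heading_change_rate,
                "revisit_fraction": m.revisit_fraction,
            }
        )
    return pd.DataFrame(rows)


def compare_cohorts(
    cohorts: Mapping[str, CohortResult | Sequence[SimulatedTrack]],
    cell_size: float = 0.5,
) -> FateComparison:
    """Fate table and metric summaries (mean/sd) across ≥ 2 named cohorts."""
    if len(cohorts) < 2:
        raise ValueError("compare_cohorts needs at least two cohorts")
    fate_rows = []
    summary_rows = []
    for name, cohort in cohorts.items():
        tracks = cohort.tracks if isinstance(cohort, CohortResult) else list(cohort)
        if not tracks:
            raise ValueError(f"cohort {name!r} is empty")
        counts = {"intake": 0, "bypass": 0, "undetermined": 0}
        for t in tracks:
            counts[t.fate] += 1
        n = len(tracks)
        fate_rows.append(
            {
                "cohort": name,
                "n_tracks": n,
                **counts,
                **{f"prop_{k}": v / n for k, v in counts.items()},
            }
        )
        mf = _metrics_frame(tracks, cell_size)
        for col in mf.columns:
            summary_rows.append(
                {
                    "cohort": name,
                    "metric": col,
                    "mean": float(mf[col].mean()),
                    "sd": float(mf[col].std(ddof=1)) if len(mf) > 1 else 0.0,
                }
            )
    return FateComparison(
        fate_table=pd.DataFrame(fate_rows),
        metric_summary=pd.DataFrame(summary_rows),
    )


def matched_simulation(
    observed_track: pd.DataFrame,
    scenario: FlowScenario,
    follow_model: BehaviourProbabilityModel,
    direction_model: BehaviourProbabilityModel,
    n_replicates: int = 3,
    seed: int = 0,
    tolerance: float = 20.0,
) -> tuple[list[SimulatedTrack], pd.DataFrame]:
    """Replicate one observed track under matched initial conditions.

    Replicates start at the observed track's first cell with the step
    budget set to the observed step count, mirroring the per-individual
    comparison panels of field evaluations.  Returns the replicate tracks
    and a side-by-side metrics table (observed row first).
    """
    steps = cellize_track(observed_track, scenario)
    if not steps:
        raise ValueError("observed track does not map into the scenario grid")
    observed_cells = [steps[0].from_cell] + [s.to_cell for s in steps]
    start = observed_cells[0]
    if not scenario.is_active(start):
        raise ValueError(f"observed start cell {start} is not active")
    config = SimConfig(
        start_cells=[start],
        replicates_per_start=n_replicates,
        max_steps=len(observed_cells) - 1,
        tolerance=tolerance,
        seed=seed,
        mode="behaviour",
    )
    replicates = []
    for rep in range(n_replicates):
        rng = _track_rng(seed, start, rep)
        replicates.append(
            simulate_smolt(
                config, start, follow_model, direction_model, scenario, rng, replicate=rep
            )
        )
    rows = []
    for label, cells in [("observed", observed_cells)] + [
        (f"replicate_{i}", t.cells) for i, t in enumerate(replicates)
    ]:
        m = track_metrics(cells, scenario.cell_size)
        rows.append(
            {
                "track": label,
                "n_steps": m.n_steps,
                "path_length": m.path_length,
                "net_displacement": m.net_displacement,
                "sinuosity": m.sinuosity,
                "heading_change_rate": m.heading_change_rate,
                "revisit_fraction": m.revisit_fraction,
            }
        )
    return replicates, pd.DataFrame(rows)
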