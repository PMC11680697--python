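import numpy as np
import pytest
from scipy.stats import chisquare

import smoltsim as ss
from smoltsim.hydraulic_field import HydraulicCell
from smoltsim.ibm_simulator import SmoltState, _track_rng

from conftest import uniform_scenario

HYD = HydraulicCell(1.0, 0.0, 0.0, 0.01)


def stub_models(p_follow, p_random):
    return ss.ConstantProbabilityModel(p_follow), ss.ConstantProbabilityModel(p_random)


class TestDecideStep:
    def test_degenerate_follow_always_follows(self):
        fm, dm = stub_models(1.0, 0.5)
        state = SmoltState(cell=(2, 2))
        rng = np.random.default_rng(0)
        for _ in range(50):
            label, heading = ss.decide_step(state, HYD, fm, dm, 20.0, rng)
            assert label is ss.Behaviour.FOLLOW
            assert ss.circular_difference(heading, 0.0) <= 20.0

    def test_always_random_excludes_flow_arc(self):
        fm, dm = stub_models(0.0, 1.0)
        state = SmoltState(cell=(2, 2))
        rng = np.random.default_rng(1)
        for _ in range(200):
            label, heading = ss.decide_step(state, HYD, fm, dm, 20.0, rng)
            assert label is ss.Behaviour.NONDIRECTIONAL
            assert ss.circular_difference(heading, 0.0) > 20.0

    def test_first_nonfollow_random_then_keep(self):
        fm, dm = stub_models(0.0, 0.0)
        state = SmoltState(cell=(2, 2))
        rng = np.random.default_rng(2)
        label0, heading0 = ss.decide_step(state, HYD, fm, dm, 20.0, rng)
        assert label0 is ss.Behaviour.NONDIRECTIONAL  # forced random at bout start
        for _ in range(20):
            label, heading = ss.decide_step(state, HYD, fm, dm, 20.0, rng)
            assert label is ss.Behaviour.DIRECTIONAL
            assert heading == heading0

    def test_follow_clears_bout_rearming_forced_random(self):
        state = SmoltState(cell=(2, 2))
        rng = np.random.default_rng(3)
        fm1, dm0 = stub_models(1.0, 0.0)
        fm0, _ = stub_models(0.0, 0.0)
        ss.decide_step(state, HYD, fm0, dm0, 20.0, rng)  # enter a bout
        assert state.in_nonfollow_bout
        ss.decide_step(state, HYD, fm1, dm0, 20.0, rng)  # FOLLOW ends the bout
        assert not state.in_nonfollow_bout
        label, _ = ss.decide_step(state, HYD, fm0, dm0, 20.0, rng)
        assert label is ss.Behaviour.NONDIRECTIONAL  # forced again in the new bout

    def test_absent_cell_rejected(self):
        fm, dm = stub_models(0.5, 0.5)
        nan = float("nan")
        nan_cell = HydraulicCell(nan, nan, nan, nan)
        with pytest.raises(ValueError):
            ss.decide_step(SmoltState(cell=(0, 0)), nan_cell, fm, dm, 20.0,
                           np.random.default_rng(0))


class TestDrawRandomHeading:
    def test_exclusion_arc(self):
        rng = np.random.default_rng(0)
        draws = [ss.draw_random_heading(0.0, 20.0, rng) for _ in range(10_000)]
        assert min(ss.circular_difference(d, 0.0) for d in draws) > 20.0

    def test_uniform_over_allowed_arc(self):
        rng = np.random.default_rng(1)
        flow = 90.0
        draws = np.array([ss.draw_random_heading(flow, 20.0, rng) for _ in range(20_000)])
        # map to offset from flow in (20, 340), bin and chi-square against uniform
        offsets = (draws - flow) % 360.0
        counts, _ = np.histogram(offsets, bins=np.linspace(20.0, 340.0, 17))
        assert chisquare(counts).pvalue > 0.01

    def test_zero_tolerance_limit(self):
        rng = np.random.default_rng(2)
        draws = [ss.draw_random_heading(45.0, 0.0, rng) for _ in range(1000)]
        assert all(0.0 <= d < 360.0 for d in draws)
        assert all(d != 45.0 for d in draws)


class TestMove:
    @pytest.mark.parametrize(
        ("heading", "expected"),
        [
            (0.0, (2, 3)),  # east
            (45.0, (3, 3)),  # diagonal
            (90.0, (3, 2)),
            (180.0, (2, 1)),
            (270.0, (1, 2)),
            (22.0, (2, 3)),  # nearest bearing: |22-0| < |22-45|
            (23.0, (3, 3)),
            (22.5, (2, 3)),  # exact tie: clockwise-first
        ],
    )
    def test_nearest_bearing_selection(self, heading, expected, eastward):
        state = SmoltState(cell=(2, 2))
        assert ss.move(state, heading, eastward) == expected

    def test_dry_neighbour_falls_back_to_next_best(self, channel):
        # row 1 borders the dry bank at row 0; heading 270 points into it
        state = SmoltState(cell=(1, 10))
        nxt = ss.move(state, 270.0, channel)
        assert nxt is not None and channel.is_active(nxt)
        assert nxt in {(1, 9), (1, 11)}  # 180° and 0° are the next-nearest bearings

    def test_no_active_neighbour_terminates(self):
        u = np.full((3, 3), np.nan)
        u[1, 1] = 1.0
        sc = ss.FlowScenario(u=u, v=u.copy(), w=u.copy(), tke=np.abs(u.copy()))
        assert ss.move(SmoltState(cell=(1, 1)), 0.0, sc) is None


class TestSimulateSmolt:
    def test_drift_exits_east_with_monotone_columns(self):
        sc = uniform_scenario(n_rows=5, n_cols=20)
        config = ss.SimConfig(start_cells=[(2, 0)], max_steps=100, seed=0, mode="drift_only")
        rng = _track_rng(0, (2, 0), 0)
        track = ss.simulate_smolt(config, (2, 0), None, None, sc, rng)
        assert track.termination == "exited"
        assert track.n_steps <= 25
        cols = [c for _, c in track.cells]
        assert cols == sorted(cols)
        assert track.fate == "bypass"

    def test_max_steps_termination(self, eastward):
        fm, dm = stub_models(0.0, 1.0)  # perpetual random headings
        config = ss.SimConfig(start_cells=[(2, 2)], max_steps=3, seed=1)
        rng = _track_rng(1, (2, 2), 0)
        track = ss.simulate_smolt(config, (2, 2), fm, dm, eastward, rng)
        if track.termination == "max_steps_reached":
            assert len(track.cells) == 4
        else:  # may stumble onto the exit boundary
            assert track.cells[-1][1] == 7

    def test_seed_determinism(self, channel):
        fm, dm = stub_models(0.7, 0.4)
        config = ss.SimConfig(start_cells=[(10, 1)], max_steps=200, seed=5)
        t1 = ss.simulate_smolt(config, (10, 1), fm, dm, channel, _track_rng(5, (10, 1), 0))
        t2 = ss.simulate_smolt(config, (10, 1), fm, dm, channel, _track_rng(5, (10, 1), 0))
        assert t1.cells == t2.cells
        assert t1.headings == t2.headings

    def test_start_on_absent_cell_rejected(self, channel):
        config = ss.SimConfig(start_cells=[(0, 0)], seed=0, mode="drift_only")
        with pytest.raises(ValueError):
            ss.simulate_smolt(config, (0, 0), None, None, channel, _track_rng(0, (0, 0), 0))

    def test_step_adjacency_chebyshev_one(self, channel):
        fm, dm = stub_models(0.6, 0.5)
        config = ss.SimConfig(
            start_cells=[(5, 1), (14, 1)], replicates_per_start=3, max_steps=300, seed=2
        )
        cohort = ss.simulate_cohort(config, fm, dm, channel)
        for track in cohort.tracks:
            for a, b in zip(track.cells, track.cells[1:]):
                assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1

    def test_follow_decisions_stay_within_tolerance_of_flow(self, channel):
        fm, dm = stub_models(0.8, 0.5)
        config = ss.SimConfig(start_cells=[(10, 1)], max_steps=300, seed=3)
        track = ss.simulate_smolt(
            config, (10, 1), fm, dm, channel, _track_rng(3, (10, 1), 0)
        )
        for cell, label, heading in zip(track.cells, track.behaviour_log, track.headings):
            flow = ss.flow_heading(channel, cell)
            if label is ss.Behaviour.FOLLOW:
                assert ss.circular_difference(heading, flow) <= 20.0 + 1e-9
            elif label is ss.Behaviour.NONDIRECTIONAL:
                assert ss.circular_difference(heading, flow) > 20.0


class TestSimulateCohort:
    def test_four_starts_five_replicates_is_twenty_tracks(self, channel):
        fm, dm = stub_models(0.9, 0.5)
        starts = [(4, 1), (8, 1), (12, 1), (16, 1)]
        config = ss.SimConfig(start_cells=starts, replicates_per_start=5, seed=0)
        cohort = ss.simulate_cohort(config, fm, dm, channel)
        assert len(cohort.tracks) == 20
        assert sum(cohort.fate_counts.values()) == 20

    def test_fate_partition_conservation(self, channel):
        config = ss.SimConfig(
            start_cells=[(10, 1)], replicates_per_start=200, max_steps=150, seed=1,
            mode="drift_only",
        )
        cohort = ss.simulate_cohort(config, None, None, channel)
        assert len(cohort.tracks) == 200
        assert sum(cohort.fate_counts.values()) == 200
        assert set(cohort.fate_counts) == {"intake", "bypass", "undetermined"}

    def test_start_order_invariance(self, channel):
        fm, dm = stub_models(0.7, 0.5)
        starts = [(4, 1), (8, 1), (12, 1)]
        c1 = ss.simulate_cohort(
            ss.SimConfig(start_cells=starts, replicates_per_start=2, seed=9), fm, dm, channel
        )
        c2 = ss.simulate_cohort(
            ss.SimConfig(start_cells=starts[::-1], replicates_per_start=2, seed=9),
            fm, dm, channel,
        )
        key = lambda t: (t.start_cell, t.replicate)
        cells1 = {key(t): t.cells for t in c1.tracks}
        cells2 = {key(t): t.cells for t in c2.tracks}
        assert cells1 == cells2


class TestDriftEquivalence:
    def test_stub_follow_model_reproduces_drift_mode(self):
        sc = ss.make_channel_field(ss.SyntheticFieldSpec(n_rows=20, n_cols=50))
        starts = [(5, 1), (10, 1), (15, 1)]
        fm, dm = stub_models(1.0, 0.0)
        behaviour = ss.simulate_cohort(
            ss.SimConfig(start_cells=starts, replicates_per_start=3, seed=4,
                         mode="behaviour"),
            fm, dm, sc,
        )
        drift = ss.simulate_cohort(
            ss.SimConfig(start_cells=starts, replicates_per_start=3, seed=4,
                         mode="drift_only"),
            None, None, sc,
        )
        for tb, td in zip(behaviour.tracks, drift.tracks):
            assert tb.cells == td.cells
            assert tb.headings == td.headings
        assert behaviour.fate_counts == drift.fate_counts


class TestBehaviourOrdering:
    def test_low_follow_probability_increases_sinuosity(self, channel):
        starts = [(10, 1)]
        high = ss.simulate_cohort(
            ss.SimConfig(start_cells=starts, replicates_per_start=10, max_steps=250,
                         seed=6),
            *stub_models(0.95, 0.5), channel,
        )
        low = ss.simulate_cohort(
            ss.SimConfig(start_cells=starts, replicates_per_start=10, max_steps=250,
                         seed=6),
            *stub_models(0.4, 0.5), channel,
        )

        def mean_sinuosity(cohort):
            vals = [
                ss.track_metrics(t.cells, channel.cell_size).sinuosity
                for t in cohort.tracks
                if len(t.cells) > 2 and not ss.track_metrics(t.cells).degenerate
            ]
            return np.mean(vals)

        assert mean_sinuosity(high) < mean_sinuosity(low)


def test_classify_fate_regions(channel):
    intake_cell = tuple(np.argwhere(channel.regions["intake"])[0])
    exit_cell = tuple(np.argwhere(channel.regions["exit_boundary"])[0])
    mk = lambda cells: ss.SimulatedTrack(
        start_cell=cells[0], cells=list(cells), behaviour_log=[], headings=[],
        termination="exited", fate="undetermined",
    )
    assert ss.classify_fate(mk([(5, 5), intake_cell]), channel) == "intake"
    assert ss.classify_fate(mk([(5, 5), exit_cell]), channel) == "bypass"
    assert ss.classify_fate(mk([(5, 5), (6, 6)]), channel) == "undetermined"
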