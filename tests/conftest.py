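import numpy as np
import pytest

import smoltsim as ss


def uniform_scenario(
    n_rows: int = 5,
    n_cols: int = 8,
    u: float = 1.0,
    v: float = 0.0,
    cell_size: float = 0.5,
    with_regions: bool = True,
) -> ss.FlowScenario:
    """A uniform flow field with no dry cells; exit boundary on the last column."""
    shape = (n_rows, n_cols)
    regions = {}
    if with_regions:
        exit_mask = np.zeros(shape, dtype=bool)
        exit_mask[:, -1] = True
        intake = np.zeros(shape, dtype=bool)
        regions = {"exit_boundary": exit_mask, "intake": intake}
    return ss.FlowScenario(
        u=np.full(shape, u),
        v=np.full(shape, v),
        w=np.zeros(shape),
        tke=np.full(shape, 0.01),
        cell_size=cell_size,
        regions=regions,
    )


@pytest.fixture
def eastward():
    return uniform_scenario()


@pytest.fixture(scope="session")
def channel():
    """Default synthetic channel-with-intake scenario."""
    return ss.make_channel_field(ss.SyntheticFieldSpec())


@pytest.fixture(scope="session")
def truth_tracks(channel):
    """A moderate synthetic cohort with its hidden truth labels."""
    truth = ss.TruthParams()
    tracks, steps = ss.generate_truth_tracks(
        channel, truth, n_fish=40, max_steps=150, seed=7
    )
    return tracks, steps, truth
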