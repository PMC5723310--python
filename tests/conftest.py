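import numpy as np
import pytest

from lrckit.kinetics import LabelDecayParams
from lrckit.synthetic import (
    BrduSimConfig,
    FlowSimConfig,
    TissueSimConfig,
    gen_brdu_records,
    gen_flow_events,
    gen_tissue_map,
)


@pytest.fixture(scope="session")
def default_decay() -> LabelDecayParams:
    return LabelDecayParams(half_life_days=24.0, pulse_intensity_I0=1000.0, chase_days=112.0)


@pytest.fixture(scope="session")
def flow_tables():
    """A moderately sized fully labeled event table + control (shared, read-only)."""
    cfg = FlowSimConfig(n_events_per_subset=20_000, labeling_efficiency=1.0, seed=11)
    events, control = gen_flow_events(cfg)
    return cfg, events, control


@pytest.fixture(scope="session")
def small_tissue_map():
    """One default-geometry tissue section with 2000 clustered points."""
    cfg = TissueSimConfig(n_lrc=2000, seed=5)
    return cfg, gen_tissue_map(cfg)


@pytest.fixture(scope="session")
def brdu_records():
    cfg = BrduSimConfig(n_per_group=4000, seed=3)
    return cfg, gen_brdu_records(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
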