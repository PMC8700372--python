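from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from passdisrupt import MatchMeta, SimConfig, TrackingSeries, simulate_match

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def meta() -> MatchMeta:
    return MatchMeta()


@pytest.fixture(scope="session")
def toy_events_path() -> Path:
    return DATA_DIR / "toy_events.csv"


def make_series(xy_by_entity: dict, times, meta: MatchMeta | None = None,
                possession=None) -> TrackingSeries:
    """Build a TrackingSeries from {(team, pid): [(x, y), ...]} literals."""
    meta = meta or MatchMeta()
    entities = list(xy_by_entity)
    if ("ball", "ball") not in entities:
        entities.append(("ball", "ball"))
        xy_by_entity = dict(xy_by_entity)
        xy_by_entity[("ball", "ball")] = [(0.0, 0.0)] * len(times)
    xy = np.stack([np.asarray(xy_by_entity[e], dtype=float) for e in entities], axis=1)
    poss = None
    if possession is not None:
        poss = np.asarray(possession, dtype=object)
    return TrackingSeries(times=np.asarray(times, float), entities=entities, xy=xy,
                          meta=meta, possession=poss)


@pytest.fixture(scope="session")
def default_match():
    """One default-condition synthetic match (noisy, mixed attack classes)."""
    return simulate_match(SimConfig(seed=42))


@pytest.fixture(scope="session")
def analytic_match():
    """Noise-free match with a deterministic 2 m disruption response."""
    return simulate_match(SimConfig.analytic(seed=7, shift=2.0, shift_sd=0.0))
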