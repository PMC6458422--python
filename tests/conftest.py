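import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lemurmove as lm

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_shaped_dataset() -> lm.SimulatedDataset:
    """One full study-design simulation (4 groups, 167 movements), shared."""
    return lm.simulate_dataset(lm.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_group() -> lm.GroupComposition:
    """A single group of 8 (3 females, 3 males, 2 juveniles)."""
    return lm.make_groups(lm.SimulationConfig(groups=((3, 3, 2),)))[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_event(
    event_id: str,
    group_id: str,
    joined_latencies: dict[str, float],
    initiator: str,
    non_joiners: tuple[str, ...] = (),
    dist_to_initiator: dict[str, lm.DistanceCategory] | None = None,
    dist_to_predecessor: dict[str, lm.DistanceCategory] | None = None,
) -> lm.DepartureEvent:
    """Assemble a valid DepartureEvent from bare latencies."""
    d_ini = dist_to_initiator or {}
    d_pre = dist_to_predecessor or {}
    records = []
    for ind, lat in joined_latencies.items():
        records.append(
            lm.DepartureRecord(
                event_id=event_id,
                individual_id=ind,
                joined=True,
                is_initiator=(ind == initiator),
                latency_s=lat,
                dist_to_initiator=d_ini.get(ind),
                dist_to_predecessor=d_pre.get(ind),
            )
        )
    for ind in non_joiners:
        records.append(
            lm.DepartureRecord(
                event_id=event_id,
                individual_id=ind,
                joined=False,
                dist_to_initiator=d_ini.get(ind),
            )
        )
    return lm.DepartureEvent(event_id=event_id, group_id=group_id, records=records)
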