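from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from wadertherm.appendages import CounterCurrentParams
from wadertherm.experiments import ChamberCurve, chamber_sweep
from wadertherm.geometry import BodyPlan
from wadertherm.io import load_crane


@pytest.fixture(scope="session")
def female() -> tuple[BodyPlan, CounterCurrentParams]:
    return load_crane("female")


@pytest.fixture(scope="session")
def male() -> tuple[BodyPlan, CounterCurrentParams]:
    return load_crane("male")


@pytest.fixture(scope="session")
def chamber_curves(female):
    """Lazily computed, session-cached chamber sweeps for the female crane.

    Keys: (wading option, counter_current flag).
    """
    plan, cc = female
    cache: dict[tuple[str, bool], ChamberCurve] = {}

    def get(wading: str = "none", counter_current: bool = True) -> ChamberCurve:
        key = (wading, counter_current)
        if key not in cache:
            cache[key] = chamber_sweep(
                plan, cc, wading=wading, counter_current=counter_current
            )
        return cache[key]

    return get
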