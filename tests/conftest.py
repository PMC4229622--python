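import random

import pytest

from acinarfate.models import ACINAR_RULES, Scenario, build_acinar, scenario_run
from acinarfate.transition_context import FormalContext


@pytest.fixture(scope="session")
def acinar():
    return build_acinar()


@pytest.fixture(scope="session")
def acinar_rule_lines():
    return [ln for ln in ACINAR_RULES.splitlines() if ln.strip()]


@pytest.fixture(scope="session")
def runs():
    """Trajectories for the basic and antioxidant scenarios (acinar)."""
    return {
        (b, m): scenario_run(Scenario(b, m))
        for b in (0, 1, 2)
        for m in ("normal", "inhibited", "added")
    }


def random_context(rng: random.Random, max_objects=6, max_attributes=5) -> FormalContext:
    n_obj = rng.randint(1, max_objects)
    n_attr = rng.randint(1, max_attributes)
    rows = tuple(rng.getrandbits(n_attr) for _ in range(n_obj))
    return FormalContext(
        tuple(f"g{i}" for i in range(n_obj)),
        tuple(f"m{i}" for i in range(n_attr)),
        rows,
    )
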