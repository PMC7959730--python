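import numpy as np
import pytest

from lqrad import StratumSpec
from lqrad.datasets import organoid_parameters


def spawn_seeds(master: int, n: int) -> list[int]:
    """Independent child seeds below 2**31 derived from one master seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(master).spawn(n)]


@pytest.fixture(scope="session")
def organoid_strata() -> tuple[StratumSpec, ...]:
    """The four published organoid parameter sets as simulation strata."""
    return tuple(
        StratumSpec("organoid", row.oxygen_condition, int(row.assay_day), row.alpha, row.beta)
        for row in organoid_parameters().itertuples()
    )


@pytest.fixture()
def hypoxic_d21_stratum() -> StratumSpec:
    return StratumSpec("organoid", "hypoxic_1pct", 21, 0.0254, 0.0013)
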