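import numpy as np
import pytest

from mekfit.reaction_model import SPECIES, Trajectory


def make_trajectory(times, series: dict[str, np.ndarray]) -> Trajectory:
    """Hand-built trajectory: named species series, all others zero."""
    times = np.asarray(times, dtype=float)
    values = np.zeros((len(times), len(SPECIES)))
    for name, ys in series.items():
        values[:, SPECIES.index(name)] = ys
    return Trajectory(times=times, values=values, species=SPECIES)


@pytest.fixture
def wt_trajectory():
    """One WT reference simulation shared across tests."""
    from mekfit.reaction_model import build_variant_network, simulate

    times = np.linspace(0.0, 3600.0, 61)
    return simulate(build_variant_network("WT"), times=times)
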