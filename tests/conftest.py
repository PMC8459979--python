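from fractions import Fraction

import pytest

from isoflux.headspace import FlowConfig
from isoflux.simulate import InstrumentSpec


def brute_force_mix_fraction(amounts, fractions, n_molecules=10**6):
    """Integer-molecule counting oracle for pool mixing.

    Scales the pools to at most ``n_molecules`` discrete molecules, rounds
    each pool's molecule and heavy-isotope counts to integers, and returns
    the exact rational heavy fraction of the union.  Agreement with the
    analytic mixer is limited by the rounding, ~1/n_molecules.
    """
    total = sum(amounts)
    scale = n_molecules / total
    n = [round(a * scale) for a in amounts]
    heavy = [round(ni * xi) for ni, xi in zip(n, fractions)]
    return Fraction(sum(heavy), sum(n))


@pytest.fixture
def instrument():
    """Default accumulate-release instrument used by the simulator tests."""
    return InstrumentSpec(
        flow=FlowConfig(
            flow_rate_L_min=0.35,
            headspace_volume_L=0.06,
            cycle_length_s=900.0,
            mode="accumulate_release",
        )
    )


@pytest.fixture
def continuous_instrument():
    return InstrumentSpec(
        flow=FlowConfig(
            flow_rate_L_min=0.5,
            headspace_volume_L=0.06,
            cycle_length_s=900.0,
            mode="continuous_flow",
        )
    )
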