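import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ripfit.fec_simulator import SimulationConfig, simulate_cycle
from ripfit.rip_analysis import detect_transitions
from ripfit.wlc_fitting import cycle_delta_lc, fit_cycle_branches

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.filter_too_much, HealthCheck.too_slow],
)
settings.load_profile("default")

logging.getLogger("ripfit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def analyzed_cycles(sim_config):
    """40 default stretch-relax cycles run through detection + fitting;
    shared across detection/fitting/classification tests."""
    out = []
    for i in range(40):
        stretch, relax, truth = simulate_cycle(sim_config, 20_000 + i)
        trans = detect_transitions(stretch)
        fits = fit_cycle_branches(stretch, trans, sim_config.tether)
        result = cycle_delta_lc(trans, fits, stretch)
        out.append(
            {
                "stretch": stretch,
                "relax": relax,
                "truth": truth,
                "transitions": trans,
                "fits": fits,
                "result": result,
            }
        )
    return out
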