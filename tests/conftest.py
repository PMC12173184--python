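"""Shared fixtures: a few session-scoped solver runs reused across tests.

Solves are the expensive step, so the canonical study-channel runs
(1.2 x 1.25 mm, 4 uL/min) and the unit square runs are computed once.
"""

import pytest

from oocflow import solve_for_flow_rate, study_case
from oocflow.geometry import ChannelGeometry
from oocflow.rheology import PowerLawFluid
from oocflow.units import ul_per_min_to_m3_per_s

Q_4UL = ul_per_min_to_m3_per_s(4.0)


@pytest.fixture(scope="session")
def lit_solution():
    """Newtonian 'literature' viscosity in the study channel at 4 uL/min."""
    sc = study_case("literature")
    return solve_for_flow_rate(sc.geometry, sc.fluid, sc.flow_rate, 2e-5)


@pytest.fixture(scope="session")
def plug_solution():
    """Strongly shear-thinning medium (n = 0.31) in the study channel."""
    sc = study_case("DMEM+10% FBS")
    return solve_for_flow_rate(sc.geometry, sc.fluid, sc.flow_rate, 2e-5)


@pytest.fixture(scope="session")
def body_temp_solution():
    """Medium at body temperature (n = 0.54) in the study channel."""
    sc = study_case("DMEM+10% FBS 37C")
    return solve_for_flow_rate(sc.geometry, sc.fluid, sc.flow_rate, 2e-5)


@pytest.fixture(scope="session")
def square_solutions():
    """1 mm square channel at 4 uL/min for the three reference flow indices."""
    geom = ChannelGeometry(w=1e-3, h=1e-3)
    fluids = {
        "newtonian": PowerLawFluid(K=1.0e-3, n=1.0, label="water"),
        "n0.54": PowerLawFluid(K=0.005, n=0.54),
        "n0.31": PowerLawFluid(K=0.028, n=0.31),
    }
    return {
        name: solve_for_flow_rate(geom, fl, Q_4UL, 1e-5)
        for name, fl in fluids.items()
    }
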