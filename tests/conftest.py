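import numpy as np
import pytest

from tumorflux.dynamics import (
    DosingSchedule,
    default_death,
    default_growth,
    default_initial_state,
    default_perfusion,
    simulate,
)
from tumorflux.kinetics import load_default_model
from tumorflux.network import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    load_default_network,
)
from tumorflux.scenarios import HIGH_DOSE_MM


@pytest.fixture(scope="session")
def net():
    return load_default_network()


@pytest.fixture(scope="session")
def model(net):
    return load_default_model(net)


@pytest.fixture(scope="session")
def control_traj(net, model):
    """Calibrated control (PBS) run, day 10 to 59."""
    perf = default_perfusion(net)
    return simulate(
        model, perf, default_growth(), default_death(),
        default_initial_state(net, perf=perf),
        DosingSchedule(12.0, {}), 10.0, 59.0,
    )


@pytest.fixture(scope="session")
def therapy_traj(net, model):
    """Full therapy (METABLOC + high metformin + high diclofenac) run."""
    perf = default_perfusion(net)
    return simulate(
        model, perf, default_growth(), default_death(),
        default_initial_state(net, perf=perf),
        DosingSchedule(12.0, dict(HIGH_DOSE_MM)), 10.0, 59.0,
    )


@pytest.fixture(scope="session")
def efms(net):
    from tumorflux.structural import elementary_flux_modes

    return elementary_flux_modes(net)


def make_net(metabolites, reactions, biomass_id=None):
    """Small-network builder for structural tests.

    metabolites: list of (id, compartment); reactions: list of
    (id, stoichiometry-dict, reversible).
    """
    mets = [Metabolite(mid, compartment=comp) for mid, comp in metabolites]
    rxns = [Reaction(rid, dict(st), reversible=rev)
            for rid, st, rev in reactions]
    bid = biomass_id if biomass_id is not None else rxns[-1].id
    return MetabolicNetwork(mets, rxns, biomass_id=bid)


def at_day(traj, day, series=None):
    i = int(np.argmin(np.abs(traj.times_day - day)))
    if series is None:
        return float(traj.V_tumor[i])
    return float(series[i])
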