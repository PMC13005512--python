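"""Shared fixtures: toy network, disease models, flux ensembles.

Everything is generated programmatically and seeded; session scope keeps
the entropic solves from being repeated across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaucherflux.disease import ScalingScheme, build_disease_model
from gaucherflux.ensemble import SimulationSetup, simulate_condition_ensemble
from gaucherflux.model import MetabolicModel, Reaction
from gaucherflux.synthetic import (
    default_differential_expression,
    make_toy_network,
)


@pytest.fixture(scope="session")
def toy():
    """(model, manifest) of the default toy macrophage network."""
    return make_toy_network()


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_manifest(toy):
    return toy[1]


@pytest.fixture(scope="session")
def setup():
    return SimulationSetup()


@pytest.fixture(scope="session")
def planted_de(toy_manifest):
    return default_differential_expression(toy_manifest)


@pytest.fixture(scope="session")
def gd_model(toy_model, planted_de, setup):
    return build_disease_model(
        toy_model, planted_de, ScalingScheme(), setup=setup, ganglioside_uptake=1.0
    )


@pytest.fixture(scope="session")
def control_prepared(toy_model, setup):
    return setup.apply(toy_model, ganglioside_uptake=1.0)


@pytest.fixture(scope="session")
def condition_ensembles(toy_model, gd_model, setup):
    """(control, GD) entropic flux ensembles, 10 members each."""
    ctrl = simulate_condition_ensemble(
        toy_model, setup, 10, seed=101, condition="control"
    )
    gd = simulate_condition_ensemble(gd_model, setup, 10, seed=202, condition="GD")
    return ctrl, gd


@pytest.fixture()
def chain_model():
    """Linear chain EX_a (uptake 10) -> A -> B -> EX_b, fully consistent."""
    m = MetabolicModel("chain")
    m.add_reaction(Reaction("EX_a", {"a[e]": -1}, -10, 0))
    m.add_reaction(Reaction("T_a", {"a[e]": -1, "a[c]": 1}, 0, 1000))
    m.add_reaction(Reaction("CONV", {"a[c]": -1, "b[c]": 1}, 0, 1000, gpr="G1"))
    m.add_reaction(Reaction("T_b", {"b[c]": -1, "b[e]": 1}, 0, 1000))
    m.add_reaction(Reaction("EX_b", {"b[e]": -1}, 0, 1000))
    return m


def random_toy_lp_model(seed: int, n_mets: int = 6, n_rxns: int = 10) -> MetabolicModel:
    """Random consistent conversion network for solver cross-checks."""
    rng = np.random.default_rng(seed)
    mets = [f"m{i}[c]" for i in range(n_mets)]
    model = MetabolicModel(id=f"lp_{seed}")
    model.add_reaction(Reaction("EX_in", {mets[0]: -1}, -float(rng.uniform(5, 15)), 0))
    model.add_reaction(Reaction("EX_out", {mets[-1]: -1}, 0, 1000))
    for i in range(n_rxns):
        a, b = rng.choice(n_mets, size=2, replace=False)
        if a > b:
            a, b = b, a
        lb = 0.0 if rng.random() < 0.7 else -float(rng.uniform(1, 5))
        model.add_reaction(
            Reaction(f"R{i:02d}", {mets[a]: -1, mets[b]: 1}, lb, float(rng.uniform(2, 20)))
        )
    return model
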