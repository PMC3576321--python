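"""Shared fixtures: hand-built toy models and the default synthetic bundle."""

import numpy as np
import pytest
import scipy.sparse as sp

from adam.model import MetabolicModel
from adam.synthetic import SyntheticScenario, generate_model


def build_model(metabolites, reactions):
    """Construct a model from {rid: (stoich dict, lb, ub, obj, gpr)} entries."""
    from adam.gpr import parse_gpr

    met_idx = {m: i for i, m in enumerate(metabolites)}
    rids = list(reactions)
    rows, cols, vals = [], [], []
    lower, upper, obj = [], [], []
    gpr = {}
    for j, rid in enumerate(rids):
        stoich, lb, ub, c, rule = reactions[rid]
        for m, coeff in stoich.items():
            rows.append(met_idx[m])
            cols.append(j)
            vals.append(float(coeff))
        lower.append(lb)
        upper.append(ub)
        obj.append(c)
        if rule:
            gpr[rid] = parse_gpr(rule)
    model = MetabolicModel(
        metabolites=list(metabolites),
        reactions=rids,
        S=sp.csc_matrix((vals, (rows, cols)), shape=(len(metabolites), len(rids))),
        lower=np.array(lower),
        upper=np.array(upper),
        reversible=np.array(lower) < 0,
        objective=np.array(obj),
        gpr=gpr,
    )
    model.validate()
    return model


@pytest.fixture
def chain_model():
    """uptake(<=10) -> A -> B -> biomass: a single linear pathway."""
    return build_model(
        ["A", "B"],
        {
            "EX_A": ({"A": -1}, -10.0, 0.0, 0.0, ""),
            "R_AB": ({"A": -1, "B": 1}, 0.0, 1000.0, 0.0, "g1"),
            "BIOMASS": ({"B": -1}, 0.0, 1000.0, 1.0, ""),
        },
    )


@pytest.fixture
def diamond_model():
    """Two parallel A -> B reactions: exactly two elementary modes."""
    return build_model(
        ["A", "B"],
        {
            "EX_A": ({"A": -1}, -10.0, 0.0, 0.0, ""),
            "R1": ({"A": -1, "B": 1}, 0.0, 1000.0, 0.0, "g1"),
            "R2": ({"A": -1, "B": 1}, 0.0, 1000.0, 0.0, "g2"),
            "BIOMASS": ({"B": -1}, 0.0, 1000.0, 1.0, ""),
        },
    )


@pytest.fixture
def bypass_model():
    """Main route plus a 5%-yield-loss bypass between the same metabolites."""
    return build_model(
        ["A", "B"],
        {
            "EX_A": ({"A": -1}, -10.0, 0.0, 0.0, ""),
            "R_main": ({"A": -1, "B": 1}, 0.0, 1000.0, 0.0, ""),
            "R_byp": ({"A": -1, "B": 0.95}, 0.0, 1000.0, 0.0, ""),
            "BIOMASS": ({"B": -1}, 0.0, 1000.0, 1.0, ""),
        },
    )


@pytest.fixture(scope="session")
def default_bundle():
    """Default zero-noise scenario: model + ground truth."""
    scenario = SyntheticScenario(noise_sd=0.0)
    model, truth = generate_model(scenario)
    return scenario, model, truth
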