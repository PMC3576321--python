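"""Flux balance analysis and the dispensable/indispensable partition.

FBA solves ``max c.v  s.t.  S.v = 0,  lower <= v <= upper`` by linear
programming (HiGHS).  The partition deletes each reaction in turn
(bounds to zero, indices stable) and re-optimises: a reaction is
*dispensable* when the perturbed optimum stays at or above a threshold
fraction (default 99%) of the wild-type optimum f_max, and
*indispensable* otherwise.  Only dispensable reactions later receive
Boolean on/off variables in the network-minimisation MILP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import MetabolicModel

#: Numerical tolerance on steady-state residuals and bound violations.
FLUX_TOL = 1e-6


class InfeasibleError(RuntimeError):
    """Raised when an LP/MILP expected to be solvable is not."""


@dataclass
class FluxSolution:
    """Result of one FBA solve."""

    fluxes: pd.Series  # reaction id -> flux
    objective: float
    status: str  # "optimal" | "infeasible" | "unbounded"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_LP_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def flux_balance(
    model: MetabolicModel,
    objective: str | np.ndarray | None = None,
) -> FluxSolution:
    """Maximise an objective over the steady-state flux polytope.

    Parameters
    ----------
    objective : reaction id, coefficient vector, or None
        None uses the model's biomass objective.
    """
    if objective is None:
        c = model.objective
    elif isinstance(objective, str):
        c = np.zeros(model.n_reactions)
        c[model.reaction_index(objective)] = 1.0
    else:
        c = np.asarray(objective, float)
        if c.shape != (model.n_reactions,):
            raise ValueError("objective vector has wrong length")

    res = linprog(
        c=-c,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([model.lower, model.upper]),
        method="highs",
    )
    status = _LP_STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(
            fluxes=pd.Series(np.nan, index=model.reactions),
            objective=np.nan,
            status=status,
        )
    return FluxSolution(
        fluxes=pd.Series(res.x, index=model.reactions),
        objective=float(-res.fun),
        status="optimal",
    )


@dataclass
class DispensabilityPartition:
    """Single-deletion partition of reactions at a biomass threshold."""

    dispensable: list[str]
    indispensable: list[str]
    threshold: float
    f_max: float
    deletion_biomass_fraction: pd.Series  # reaction id -> fraction of f_max

    def __post_init__(self):
        if set(self.dispensable) & set(self.indispensable):
            raise ValueError("partition sets overlap")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid, frac in self.deletion_biomass_fraction.items():
            cls = "dispensable" if rid in set(self.dispensable) else "indispensable"
            rows.append(
                {"reaction": rid, "class": cls, "deletion_biomass_fraction": frac}
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, threshold: float, f_max: float):
        disp = df.loc[df["class"] == "dispensable", "reaction"].tolist()
        indisp = df.loc[df["class"] == "indispensable", "reaction"].tolist()
        frac = pd.Series(
            df["deletion_biomass_fraction"].to_numpy(), index=df["reaction"]
        )
        return cls(disp, indisp, threshold, f_max, frac)


def classify_dispensable(
    model: MetabolicModel, threshold: float = 0.99
) -> DispensabilityPartition:
    """Partition reactions by single-deletion effect on biomass.

    Deletes every reaction one by one (both bounds to zero) and re-runs
    FBA; a reaction is dispensable iff the perturbed biomass optimum is
    >= threshold * f_max.
    """
    base = flux_balance(model)
    if not base.optimal or base.objective <= FLUX_TOL:
        raise InfeasibleError(
            "complete network has zero or infeasible biomass optimum; "
            "the dispensability threshold is undefined"
        )
    f_max = base.objective

    dispensable, indispensable, fractions = [], [], {}
    for rid in model.reactions:
        j = model.reaction_index(rid)
        lo, hi = model.lower[j], model.upper[j]
        model.lower[j] = model.upper[j] = 0.0
        try:
            sol = flux_balance(model)
        finally:
            model.lower[j], model.upper[j] = lo, hi
        value = sol.objective if sol.optimal else 0.0
        frac = value / f_max
        fractions[rid] = frac
        # small negative tolerance so a 99.0000001%-retaining deletion
        # at threshold 0.99 is not lost to LP round-off
        if frac >= threshold - FLUX_TOL:
            dispensable.append(rid)
        else:
            indispensable.append(rid)

    return DispensabilityPartition(
        dispensable=dispensable,
        indispensable=indispensable,
        threshold=threshold,
        f_max=f_max,
        deletion_biomass_fraction=pd.Series(fractions),
    )
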