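"""Stoichiometric metabolic models: containers, TSV/SBML input, irreversible form.

The model container holds the stoichiometric matrix S (metabolites x
reactions), flux bounds, reversibility and exchange flags, the biomass
objective vector c, and optional GPR rules.  Exchange reactions follow
the signed convention of standard reconstructions: an exchange is
written ``metabolite <-> (nothing)`` with coefficient -1, so negative
flux is uptake and positive flux is secretion.

The native text dialect is three TSV files per model directory:

* ``reactions.tsv``   — id, lower, upper, reversible, objective, gpr
* ``metabolites.tsv`` — id
* ``stoichiometry.tsv`` — metabolite, reaction, coefficient

SBML (Level 3 + fbc) is read through cobrapy/libsbml.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gpr import GPRNode, parse_gpr, serialize_gpr


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class MediumError(ValueError):
    """Raised for medium specs referencing unknown exchange reactions."""


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model.

    Attributes
    ----------
    metabolites, reactions : list of str
        Row / column labels of ``S``.
    S : scipy.sparse.csc_matrix, shape (n_metabolites, n_reactions)
    lower, upper : ndarray
        Flux bounds per reaction (e.g. mmol/gDW/h).
    reversible : ndarray of bool
        True where the reaction may carry negative flux (lower < 0).
    objective : ndarray
        Biomass objective coefficients c_j.
    gpr : dict reaction id -> GPRNode
        Boolean gene association; reactions may be absent.
    """

    metabolites: list[str]
    reactions: list[str]
    S: sp.csc_matrix
    lower: np.ndarray
    upper: np.ndarray
    reversible: np.ndarray
    objective: np.ndarray
    gpr: dict[str, GPRNode] = field(default_factory=dict)

    def __post_init__(self):
        self.S = sp.csc_matrix(self.S, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        self.objective = np.asarray(self.objective, dtype=float)
        self._rxn_index = {r: j for j, r in enumerate(self.reactions)}
        self._met_index = {m: i for i, m in enumerate(self.metabolites)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def reaction_index(self, rid: str) -> int:
        return self._rxn_index[rid]

    @property
    def exchange(self) -> np.ndarray:
        """Exchange flag: reactions touching exactly one metabolite."""
        counts = np.diff(self.S.indptr)
        return counts == 1

    def exchange_ids(self) -> list[str]:
        return [r for r, flag in zip(self.reactions, self.exchange) if flag]

    def biomass_reaction(self) -> str:
        nz = np.flatnonzero(self.objective)
        if len(nz) != 1:
            raise ModelValidationError(
                f"expected exactly one objective reaction, found {len(nz)}"
            )
        return self.reactions[nz[0]]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            S=self.S.copy(),
            lower=self.lower.copy(),
            upper=self.upper.copy(),
            reversible=self.reversible.copy(),
            objective=self.objective.copy(),
            gpr=dict(self.gpr),
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        m, n = self.S.shape
        if n != len(self.reactions):
            raise ModelValidationError(
                f"S has {n} columns but model lists {len(self.reactions)} reactions"
            )
        if m != len(self.metabolites):
            raise ModelValidationError(
                f"S has {m} rows but model lists {len(self.metabolites)} metabolites"
            )
        bad = np.flatnonzero(self.lower > self.upper)
        if len(bad):
            raise ModelValidationError(
                f"lower > upper for reactions {[self.reactions[j] for j in bad]}"
            )
        if len(set(self.reactions)) != n:
            raise ModelValidationError("duplicate reaction ids")
        if len(set(self.metabolites)) != m:
            raise ModelValidationError("duplicate metabolite ids")
        incons = np.flatnonzero(self.reversible != (self.lower < 0))
        if len(incons):
            raise ModelValidationError(
                "reversible flag inconsistent with lower bound for "
                f"{[self.reactions[j] for j in incons]}"
            )


@dataclass
class MediumSpec:
    """Growth-medium constraints on exchange reactions.

    Maps exchange reaction id -> (uptake bound, secretion bound) in the
    signed convention: uptake bound <= 0 <= secretion bound.
    """

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self):
        for rid, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise MediumError(f"non-finite medium bounds for {rid}")
            if not (lo <= 0.0 <= hi):
                raise MediumError(
                    f"medium bounds for {rid} must satisfy uptake <= 0 <= secretion, "
                    f"got ({lo}, {hi})"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MediumSpec":
        df = pd.read_csv(path, sep="\t", dtype={"exchange": str})
        bounds = {
            row.exchange: (float(row.lower), float(row.upper))
            for row in df.itertuples()
        }
        return cls(bounds)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"exchange": rid, "lower": lo, "upper": hi}
            for rid, (lo, hi) in self.bounds.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def load_model(path: str | Path, format: str = "tsv") -> MetabolicModel:
    """Load a metabolic model from a TSV directory or an SBML file."""
    if format == "tsv":
        return _load_tsv(Path(path))
    if format == "sbml":
        return _load_sbml(Path(path))
    raise ValueError(f"unknown model format {format!r}")


def _load_tsv(root: Path) -> MetabolicModel:
    rxn_path = root / "reactions.tsv"
    met_path = root / "metabolites.tsv"
    sto_path = root / "stoichiometry.tsv"
    for p in (rxn_path, met_path, sto_path):
        if not p.exists():
            raise FileNotFoundError(f"model file missing: {p}")
    rxns = pd.read_csv(rxn_path, sep="\t", dtype={"id": str, "gpr": str})
    mets = pd.read_csv(met_path, sep="\t", dtype={"id": str})
    sto = pd.read_csv(
        sto_path, sep="\t", dtype={"metabolite": str, "reaction": str}
    )

    metabolites = mets["id"].tolist()
    reactions = rxns["id"].tolist()
    met_idx = {m: i for i, m in enumerate(metabolites)}
    rxn_idx = {r: j for j, r in enumerate(reactions)}

    rows, cols, vals = [], [], []
    for k, row in enumerate(sto.itertuples()):
        if row.metabolite not in met_idx:
            raise ModelValidationError(
                f"{sto_path} line {k + 2}: unknown metabolite {row.metabolite!r}"
            )
        if row.reaction not in rxn_idx:
            raise ModelValidationError(
                f"{sto_path} line {k + 2}: unknown reaction {row.reaction!r}"
            )
        rows.append(met_idx[row.metabolite])
        cols.append(rxn_idx[row.reaction])
        vals.append(float(row.coefficient))
    S = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(metabolites), len(reactions))
    )

    gpr: dict[str, GPRNode] = {}
    for row in rxns.itertuples():
        rule = row.gpr
        if isinstance(rule, str) and rule.strip():
            gpr[row.id] = parse_gpr(rule)

    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        S=S,
        lower=rxns["lower"].to_numpy(float),
        upper=rxns["upper"].to_numpy(float),
        reversible=rxns["reversible"].to_numpy(bool),
        objective=rxns["objective"].to_numpy(float),
        gpr=gpr,
    )
    model.validate()
    return model


def save_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model to the three-file TSV dialect (lossless round trip)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rxn_rows = []
    for j, rid in enumerate(model.reactions):
        rxn_rows.append(
            {
                "id": rid,
                "lower": model.lower[j],
                "upper": model.upper[j],
                "reversible": bool(model.reversible[j]),
                "objective": model.objective[j],
                "gpr": serialize_gpr(model.gpr[rid]) if rid in model.gpr else "",
            }
        )
    pd.DataFrame(rxn_rows).to_csv(root / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame({"id": model.metabolites}).to_csv(
        root / "metabolites.tsv", sep="\t", index=False
    )
    coo = model.S.tocoo()
    sto = pd.DataFrame(
        {
            "metabolite": [model.metabolites[i] for i in coo.row],
            "reaction": [model.reactions[j] for j in coo.col],
            "coefficient": coo.data,
        }
    ).sort_values(["reaction", "metabolite"], kind="stable")
    sto.to_csv(root / "stoichiometry.tsv", sep="\t", index=False)


def _load_sbml(path: Path) -> MetabolicModel:
    """Read SBML Level 3 (fbc) through cobrapy and convert."""
    import cobra.io

    cb = cobra.io.read_sbml_model(str(path))
    metabolites = [m.id for m in cb.metabolites]
    reactions = [r.id for r in cb.reactions]
    met_idx = {m: i for i, m in enumerate(metabolites)}
    rows, cols, vals = [], [], []
    for j, r in enumerate(cb.reactions):
        for met, coeff in r.metabolites.items():
            rows.append(met_idx[met.id])
            cols.append(j)
            vals.append(float(coeff))
    S = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(metabolites), len(reactions))
    )
    lower = np.array([r.lower_bound for r in cb.reactions], float)
    upper = np.array([r.upper_bound for r in cb.reactions], float)
    objective = np.array([r.objective_coefficient for r in cb.reactions], float)
    gpr = {}
    for r in cb.reactions:
        rule = r.gene_reaction_rule
        if rule and rule.strip():
            gpr[r.id] = parse_gpr(rule)
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        S=S,
        lower=lower,
        upper=upper,
        reversible=lower < 0,
        objective=objective,
        gpr=gpr,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Irreversible working form
# ---------------------------------------------------------------------------

REV_SUFFIX = "__rev"


@dataclass
class SplitMap:
    """Bookkeeping for the reversible -> forward/backward split.

    ``pairs`` maps each originally reversible reaction id to its
    (forward column id, backward column id); the backward column has
    negated stoichiometry.  Downstream results are always folded back
    to original ids through this map.
    """

    pairs: dict[str, tuple[str, str]]

    def original_id(self, column_id: str) -> str:
        if column_id.endswith(REV_SUFFIX):
            return column_id[: -len(REV_SUFFIX)]
        return column_id

    def fold_support(self, column_ids) -> frozenset[str]:
        return frozenset(self.original_id(c) for c in column_ids)


def to_irreversible(model: MetabolicModel) -> tuple[MetabolicModel, SplitMap]:
    """Split reversible reactions into forward/backward nonnegative columns.

    The backward column carries negated stoichiometry with bounds
    (0, -lower).  Irreversible reactions are passed through unchanged.
    The flux cone is preserved: any original flux v maps to the split
    fluxes (max(v,0), max(-v,0)) and back via net = forward - backward.
    """
    model.validate()
    rev_idx = np.flatnonzero(model.reversible)
    if len(rev_idx) == 0:
        return model.copy(), SplitMap(pairs={})

    reactions: list[str] = []
    cols = []
    lower, upper, objective = [], [], []
    gpr: dict[str, GPRNode] = {}
    pairs: dict[str, tuple[str, str]] = {}
    Scsc = model.S
    for j, rid in enumerate(model.reactions):
        col = Scsc.getcol(j)
        reactions.append(rid)
        cols.append(col)
        lower.append(max(model.lower[j], 0.0))
        upper.append(model.upper[j])
        objective.append(model.objective[j])
        if rid in model.gpr:
            gpr[rid] = model.gpr[rid]
        if model.reversible[j]:
            bid = rid + REV_SUFFIX
            reactions.append(bid)
            cols.append(-col)
            lower.append(0.0)
            upper.append(-model.lower[j])
            objective.append(0.0)
            if rid in model.gpr:
                gpr[bid] = model.gpr[rid]
            pairs[rid] = (rid, bid)

    split = MetabolicModel(
        metabolites=list(model.metabolites),
        reactions=reactions,
        S=sp.hstack(cols, format="csc"),
        lower=np.array(lower),
        upper=np.array(upper),
        reversible=np.zeros(len(reactions), bool),
        objective=np.array(objective),
        gpr=gpr,
    )
    split.validate()
    return split, SplitMap(pairs=pairs)


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Constrain exchange reactions to a growth medium.

    Exchanges not listed in the medium have uptake closed (lower bound
    raised to 0, secretion untouched); listed exchanges receive the
    medium's bounds.  Idempotent.
    """
    out = model.copy()
    exchange_ids = set(model.exchange_ids())
    unknown = set(medium.bounds) - exchange_ids
    if unknown:
        raise MediumError(
            f"medium lists non-exchange or unknown reactions: {sorted(unknown)}"
        )
    for rid in exchange_ids:
        j = out.reaction_index(rid)
        if rid in medium.bounds:
            lo, hi = medium.bounds[rid]
            out.lower[j], out.upper[j] = lo, hi
        else:
            out.lower[j] = max(out.lower[j], 0.0)
        out.reversible[j] = out.lower[j] < 0
    out.validate()
    return out
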