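"""Minimal operating networks via bilevel optimisation.

The extraction problem: find the smallest set of reactions such that a
flux distribution maximising the data-derived weighted flux sum still
produces at least a floor amount of biomass.  Formally, with Boolean
inclusion variables y_j on *dispensable* reactions D (indispensable
reactions N are always included):

    outer:  minimise  sum_{j in D} y_j
    inner:  maximise  sum_j w_j v_j
            s.t.      S v = 0
                      c.v >= f_min
                      0 <= v_j <= u_j y_j   (j in D)
                      0 <= v_j <= u_j       (j in N)

The bilevel program is collapsed to a single-level MILP by replacing
the inner LP with its KKT-free strong-duality certificate: inner primal
feasibility + inner dual feasibility + equality of primal and dual
objectives.  Products of dual variables with Booleans arising in the
dual objective are linearised with big-M envelopes.  Ties among
equally small networks are broken by a second solve maximising the
inner objective at the optimal count, making the output well defined
up to residual degeneracy.

Solved with HiGHS through scipy.optimize.milp.  An exhaustive oracle
(`brute_force_minimal_network`) enumerates all Boolean assignments on
small models and is used throughout the test-suite to certify the
MILP construction, in particular the validity of the big-M constants.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, linprog, milp

from .fba import FLUX_TOL, InfeasibleError
from .model import MetabolicModel, SplitMap

logger = logging.getLogger(__name__)


@dataclass
class BilevelSpec:
    """One network-extraction problem: model + weights + Boolean set + floor."""

    model: MetabolicModel  # irreversible split form
    split: SplitMap
    column_weights: np.ndarray  # w per split column
    dispensable: list[str]  # ORIGINAL reaction ids carrying Booleans
    column_groups: dict[str, list[int]]  # dispensable orig id -> column indices
    f_min: float
    f_max: float

    @property
    def indispensable(self) -> list[str]:
        disp = set(self.dispensable)
        seen = set()
        out = []
        for col in self.model.reactions:
            rid = self.split.original_id(col)
            if rid not in disp and rid not in seen:
                seen.add(rid)
                out.append(rid)
        return out


def build_bilevel(
    model,
    split: SplitMap,
    weights: pd.Series,
    partition,
    f_min_fraction: float = 0.10,
    bound_cap: float | None = None,
) -> BilevelSpec:
    """Assemble the bilevel spec for one time point / condition.

    Parameters
    ----------
    model : irreversible split model (all lower bounds zero)
    weights : reaction id -> weight on ORIGINAL ids; both split columns
        of a reversible reaction inherit the reaction's weight.
    partition : DispensabilityPartition on the original model
    f_min_fraction : biomass floor as a fraction of f_max
    bound_cap : replacement for infinite upper bounds; without it an
        infinite bound is an error (big-M needs finite bounds).
    """
    if not (0 <= f_min_fraction <= 1):
        raise ValueError("f_min_fraction must lie in [0, 1]")
    if np.any(model.lower != 0):
        raise ValueError("bilevel spec requires the irreversible form (lower == 0)")
    inf_cols = np.flatnonzero(~np.isfinite(model.upper))
    if len(inf_cols):
        if bound_cap is None:
            raise ValueError(
                "infinite upper bounds on "
                f"{[model.reactions[j] for j in inf_cols]}; pass bound_cap"
            )
        model = model.copy()
        model.upper[inf_cols] = bound_cap

    col_orig = [split.original_id(c) for c in model.reactions]
    missing = sorted(set(col_orig) - set(weights.index))
    if missing:
        raise ValueError(f"weights missing for reactions {missing}")
    w = np.array([weights[rid] for rid in col_orig], float)

    groups: dict[str, list[int]] = {}
    disp = [d for d in partition.dispensable]
    disp_set = set(disp)
    for j, rid in enumerate(col_orig):
        if rid in disp_set:
            groups.setdefault(rid, []).append(j)
    disp = [d for d in disp if d in groups]  # keep model order, drop absent ids

    return BilevelSpec(
        model=model,
        split=split,
        column_weights=w,
        dispensable=disp,
        column_groups=groups,
        f_min=f_min_fraction * partition.f_max,
        f_max=partition.f_max,
    )


# ---------------------------------------------------------------------------
# Inner LP (used by the oracle and for post-hoc verification)
# ---------------------------------------------------------------------------

def solve_inner_lp(spec: BilevelSpec, y: dict[str, int] | None = None):
    """Maximise w.v over the inner polytope for a fixed Boolean assignment.

    Returns (status, v, objective); y=None means all reactions included.
    """
    model = spec.model
    upper = model.upper.copy()
    if y is not None:
        for rid, cols in spec.column_groups.items():
            if not y.get(rid, 1):
                upper[cols] = 0.0
    res = linprog(
        c=-spec.column_weights,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        A_ub=-model.objective.reshape(1, -1),
        b_ub=np.array([-spec.f_min]),
        bounds=np.column_stack([model.lower, upper]),
        method="highs",
    )
    if res.status != 0:
        return ("infeasible" if res.status == 2 else "failed", None, np.nan)
    return ("optimal", res.x, float(-res.fun))


# ---------------------------------------------------------------------------
# Single-level MILP via inner-LP duality
# ---------------------------------------------------------------------------

@dataclass
class SingleLevelMILP:
    """Dualised single-level MILP ready for the HiGHS solver.

    Variable layout: [v (n) | y (d) | lam (m) | mu (1) | eta (n) | g (nd)]
    where lam/mu/eta are duals of the inner steady-state, biomass-floor
    and upper-bound rows, and g_j linearises eta_j * y_{group(j)} on
    dispensable columns.
    """

    spec: BilevelSpec
    constraints: list[LinearConstraint]
    integrality: np.ndarray
    var_lower: np.ndarray
    var_upper: np.ndarray
    n_v: int
    n_y: int
    slice_v: slice
    slice_y: slice
    big_m: float
    disp_cols: list[int] = field(default_factory=list)


def dualize(spec: BilevelSpec, big_m: float | None = None) -> SingleLevelMILP:
    """Collapse the bilevel program to one MILP by strong duality.

    Inner primal (for fixed y):  max w.v  s.t.  S v = 0 (duals lam,
    free), -c.v <= -f_min (dual mu >= 0), v <= cap (duals eta >= 0),
    v >= 0, with cap_j = u_j*y on dispensable columns.  Dual:

        min  -f_min*mu + sum_j cap_j eta_j
        s.t. S^T lam - c mu + eta >= w,   mu, eta >= 0.

    The MILP imposes inner primal feasibility, dual feasibility, and
    the strong-duality equality; the bilinear cap terms u_j*eta_j*y
    are replaced by g_j with the standard big-M envelope.  Dual
    variables are boxed at ``big_m`` (default 1e4 * max(1, max|w|)),
    logged, and certified against the exhaustive oracle in tests.
    """
    model = spec.model
    n = model.n_reactions
    m = model.n_metabolites
    d = len(spec.dispensable)
    y_of = {rid: k for k, rid in enumerate(spec.dispensable)}
    disp_cols = [j for rid in spec.dispensable for j in spec.column_groups[rid]]
    gcol_group = [y_of[spec.split.original_id(model.reactions[j])] for j in disp_cols]
    nd = len(disp_cols)
    w = spec.column_weights
    u = model.upper
    c = model.objective

    if big_m is None:
        big_m = 1e4 * max(1.0, float(np.max(np.abs(w))) if n else 1.0)
    logger.debug("dualize: big_m=%g (n=%d, d=%d)", big_m, n, d)

    N = n + d + m + 1 + n + nd
    off_v, off_y, off_lam, off_mu, off_eta, off_g = (
        0, n, n + d, n + d + m, n + d + m + 1, n + d + m + 1 + n,
    )

    cons: list[LinearConstraint] = []

    def mat(triples, rows):
        data = [t[2] for t in triples]
        r = [t[0] for t in triples]
        col = [t[1] for t in triples]
        return sp.csr_matrix((data, (r, col)), shape=(rows, N))

    # (a) S v = 0
    Scoo = model.S.tocoo()
    A = mat(list(zip(Scoo.row, Scoo.col + off_v, Scoo.data)), m)
    cons.append(LinearConstraint(A, np.zeros(m), np.zeros(m)))

    # (b) c.v >= f_min
    tri = [(0, off_v + j, c[j]) for j in np.flatnonzero(c)]
    cons.append(LinearConstraint(mat(tri, 1), [spec.f_min], [np.inf]))

    # (c) v_j - u_j y_group <= 0 on dispensable columns
    tri = []
    for r, (j, k) in enumerate(zip(disp_cols, gcol_group)):
        tri.append((r, off_v + j, 1.0))
        tri.append((r, off_y + k, -u[j]))
    if nd:
        cons.append(LinearConstraint(mat(tri, nd), -np.inf, np.zeros(nd)))

    # (d) dual feasibility: S^T lam - c mu + eta >= w
    tri = list(zip(Scoo.col, Scoo.row + off_lam, Scoo.data))
    tri += [(j, off_mu, -c[j]) for j in np.flatnonzero(c)]
    tri += [(j, off_eta + j, 1.0) for j in range(n)]
    cons.append(LinearConstraint(mat(tri, n), w, np.inf))

    # (e) strong duality: w.v + f_min*mu - sum_N u_j eta_j - sum_D u_j g_j = 0
    disp_col_set = set(disp_cols)
    tri = [(0, off_v + j, w[j]) for j in range(n) if w[j] != 0]
    tri.append((0, off_mu, spec.f_min))
    for j in range(n):
        if j not in disp_col_set:
            tri.append((0, off_eta + j, -u[j]))
    for r, j in enumerate(disp_cols):
        tri.append((0, off_g + r, -u[j]))
    cons.append(LinearConstraint(mat(tri, 1), [0.0], [0.0]))

    if nd:
        # (f) g <= eta
        tri = []
        for r, j in enumerate(disp_cols):
            tri.append((r, off_g + r, 1.0))
            tri.append((r, off_eta + j, -1.0))
        cons.append(LinearConstraint(mat(tri, nd), -np.inf, np.zeros(nd)))
        # (g) g <= M y
        tri = []
        for r, k in enumerate(gcol_group):
            tri.append((r, off_g + r, 1.0))
            tri.append((r, off_y + k, -big_m))
        cons.append(LinearConstraint(mat(tri, nd), -np.inf, np.zeros(nd)))
        # (h) g >= eta - M (1 - y)  <=>  g - eta - M y >= -M
        tri = []
        for r, (j, k) in enumerate(zip(disp_cols, gcol_group)):
            tri.append((r, off_g + r, 1.0))
            tri.append((r, off_eta + j, -1.0))
            tri.append((r, off_y + k, -big_m))
        cons.append(
            LinearConstraint(mat(tri, nd), np.full(nd, -big_m), np.inf)
        )

    lb = np.concatenate(
        [model.lower, np.zeros(d), np.full(m, -big_m), [0.0], np.zeros(n), np.zeros(nd)]
    )
    ub = np.concatenate(
        [model.upper, np.ones(d), np.full(m, big_m), [big_m], np.full(n, big_m),
         np.full(nd, big_m)]
    )
    integrality = np.zeros(N)
    integrality[off_y : off_y + d] = 1

    return SingleLevelMILP(
        spec=spec,
        constraints=cons,
        integrality=integrality,
        var_lower=lb,
        var_upper=ub,
        n_v=n,
        n_y=d,
        slice_v=slice(off_v, off_v + n),
        slice_y=slice(off_y, off_y + d),
        big_m=big_m,
        disp_cols=disp_cols,
    )


@dataclass
class MinimalNetwork:
    """Solution of one extraction: the minimal operating network."""

    condition: str | None
    time_min: float | None
    included: list[str]  # original reaction ids
    fluxes: pd.Series  # net flux per original id (forward - backward)
    biomass: float
    inner_objective: float
    n_reactions: int
    status: str
    f_min: float
    two_cycles: list[str] = field(default_factory=list)

    @property
    def included_set(self) -> frozenset[str]:
        return frozenset(self.included)


def _solve_milp(milp_prob: SingleLevelMILP, objective: np.ndarray,
                extra: list[LinearConstraint] | None = None):
    from scipy.optimize import Bounds

    cons = milp_prob.constraints + (extra or [])
    res = milp(
        c=objective,
        constraints=cons,
        integrality=milp_prob.integrality,
        bounds=Bounds(milp_prob.var_lower, milp_prob.var_upper),
        options={"mip_rel_gap": 0.0},
    )
    return res


def extract_minimal_network(
    milp_prob: SingleLevelMILP,
    condition: str | None = None,
    time_min: float | None = None,
    verify_tol: float = 1e-5,
) -> MinimalNetwork:
    """Solve the dualised MILP lexicographically and assemble the network.

    Phase 1 minimises the number of included dispensable reactions;
    phase 2, at that count, maximises the inner weighted-flux objective.
    The returned solution is re-verified by direct substitution
    (steady state, bounds, biomass floor) and against a fresh inner-LP
    solve at the chosen Boolean assignment.
    """
    spec = milp_prob.spec
    model = spec.model
    N = len(milp_prob.var_lower)

    c1 = np.zeros(N)
    c1[milp_prob.slice_y] = 1.0
    res1 = _solve_milp(milp_prob, c1)
    if res1.status != 0:
        raise InfeasibleError(
            f"network extraction infeasible at biomass floor f_min={spec.f_min:g} "
            f"(solver: {res1.message})"
        )
    k_star = int(round(res1.x[milp_prob.slice_y].sum()))

    # phase 2: fix the count, maximise the inner objective
    c2 = np.zeros(N)
    c2[milp_prob.slice_v] = -spec.column_weights
    count_row = sp.csr_matrix(
        (np.ones(milp_prob.n_y),
         (np.zeros(milp_prob.n_y, int),
          np.arange(milp_prob.slice_y.start, milp_prob.slice_y.stop))),
        shape=(1, N),
    )
    res2 = _solve_milp(
        milp_prob, c2, extra=[LinearConstraint(count_row, [k_star], [k_star])]
    )
    if res2.status != 0:  # pragma: no cover - phase 1 proved feasibility
        raise InfeasibleError(f"tie-break phase failed: {res2.message}")

    v = res2.x[milp_prob.slice_v]
    yvec = np.round(res2.x[milp_prob.slice_y]).astype(int)
    y = dict(zip(spec.dispensable, yvec))

    _verify_solution(spec, v, y, verify_tol)

    included = sorted(
        set(spec.indispensable) | {rid for rid, on in y.items() if on}
    )
    fluxes, two_cycles = _fold_fluxes(model, spec.split, v)
    biomass = float(model.objective @ v)
    return MinimalNetwork(
        condition=condition,
        time_min=time_min,
        included=included,
        fluxes=fluxes,
        biomass=biomass,
        inner_objective=float(spec.column_weights @ v),
        n_reactions=len(included),
        status="optimal",
        f_min=spec.f_min,
        two_cycles=two_cycles,
    )


def _verify_solution(spec, v, y, tol):
    model = spec.model
    resid = np.abs(model.S @ v)
    if resid.size and resid.max() > 1e-6 * max(1.0, np.abs(v).max()):
        raise RuntimeError(f"steady-state residual {resid.max():g} exceeds tolerance")
    if (v < model.lower - 1e-6).any() or (v > model.upper + 1e-6).any():
        raise RuntimeError("flux bounds violated in MILP solution")
    biomass = float(model.objective @ v)
    if biomass < spec.f_min - 1e-6 * max(1.0, spec.f_min):
        raise RuntimeError(
            f"biomass {biomass:g} below floor {spec.f_min:g} in MILP solution"
        )
    for rid, cols in spec.column_groups.items():
        if not y[rid] and np.abs(v[cols]).max() > 1e-6:
            raise RuntimeError(f"excluded reaction {rid} carries flux")
    status, _, inner_opt = solve_inner_lp(spec, y)
    if status != "optimal":
        raise RuntimeError("inner LP infeasible at reported Boolean assignment")
    achieved = float(spec.column_weights @ v)
    if abs(achieved - inner_opt) > tol * (1.0 + abs(inner_opt)):
        raise RuntimeError(
            f"strong duality violated: w.v={achieved:g} vs inner optimum {inner_opt:g}"
        )


def _fold_fluxes(model, split: SplitMap, v):
    """Net fluxes on original ids; flags two-cycles on split pairs."""
    net: dict[str, float] = {}
    for j, col in enumerate(model.reactions):
        rid = split.original_id(col)
        sign = -1.0 if col.endswith("__rev") else 1.0
        net[rid] = net.get(rid, 0.0) + sign * v[j]
    two_cycles = []
    for rid, (fwd, bwd) in split.pairs.items():
        if fwd in model._rxn_index and bwd in model._rxn_index:
            vf = v[model.reaction_index(fwd)]
            vb = v[model.reaction_index(bwd)]
            if min(vf, vb) > 10 * FLUX_TOL:
                two_cycles.append(rid)
    if two_cycles:
        logger.warning("two-cycle flux on split pairs: %s", two_cycles)
    return pd.Series(net), two_cycles


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

@dataclass
class BruteForceResult:
    n_reactions: int  # total included reactions (|N| + sum y)
    inner_objective: float
    y: dict[str, int]
    n_feasible: int


def brute_force_minimal_network(
    spec: BilevelSpec, max_booleans: int = 12
) -> BruteForceResult:
    """Exhaustive bilevel solve: enumerate every Boolean assignment.

    For each y in {0,1}^D the inner LP (including the biomass floor) is
    solved; feasible assignments are ranked lexicographically by
    (number of included reactions, -inner objective).  Independent of
    the dualised MILP path; guards at ``max_booleans`` Booleans.
    """
    d = len(spec.dispensable)
    if d > max_booleans:
        raise ValueError(f"{d} Booleans exceed the brute-force guard {max_booleans}")
    n_indisp = len(spec.indispensable)
    best = None
    n_feasible = 0
    for bits in itertools.product((0, 1), repeat=d):
        y = dict(zip(spec.dispensable, bits))
        status, _, obj = solve_inner_lp(spec, y)
        if status != "optimal":
            continue
        n_feasible += 1
        key = (sum(bits), -obj)
        if best is None or key < best[0]:
            best = (key, y, obj)
    if best is None:
        raise InfeasibleError("no Boolean assignment satisfies the biomass floor")
    (count, _), y, obj = best
    return BruteForceResult(
        n_reactions=n_indisp + count, inner_objective=obj, y=y, n_feasible=n_feasible
    )


# ---------------------------------------------------------------------------
# Time-series driver
# ---------------------------------------------------------------------------

def run_time_series(
    model,
    split: SplitMap,
    reaction_weights: pd.DataFrame,
    partition,
    f_min_fraction: float = 0.10,
    bound_cap: float | None = None,
    big_m: float | None = None,
) -> dict[tuple[str, float], MinimalNetwork]:
    """Extract one minimal network per (condition, time point).

    Time points are solved independently (the temporal coupling lives
    in the data, not the program).  Per-key failures are collected and
    reported at the end; successful keys are returned regardless.
    """
    results: dict[tuple[str, float], MinimalNetwork] = {}
    failures: dict[tuple[str, float], str] = {}
    keys = (
        reaction_weights[["condition", "time_min"]]
        .drop_duplicates()
        .sort_values(["condition", "time_min"])
    )
    for cond, t in keys.itertuples(index=False):
        sel = reaction_weights[
            (reaction_weights["condition"] == cond)
            & (reaction_weights["time_min"] == t)
        ]
        w = pd.Series(sel["weight"].to_numpy(), index=sel["reaction"].to_numpy())
        try:
            spec = build_bilevel(
                model, split, w, partition, f_min_fraction, bound_cap=bound_cap
            )
            net = extract_minimal_network(
                dualize(spec, big_m=big_m), condition=cond, time_min=t
            )
            results[(cond, t)] = net
        except Exception as exc:  # noqa: BLE001 - per-key isolation is the contract
            failures[(cond, t)] = str(exc)
            logger.error("extraction failed for %s t=%s: %s", cond, t, exc)
    if failures:
        logger.warning(
            "%d of %d extractions failed: %s", len(failures), len(keys), failures
        )
    return results
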