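"""Elementary flux mode enumeration.

An elementary flux mode (EFM) of an irreversible network is a
support-minimal nonnegative steady-state flux vector: a minimal set of
reactions that can operate together at steady state.  The enumeration
here is the classical nullspace/double-description scheme: start from
the unit rays of the positive orthant and process the steady-state
constraint of one metabolite at a time, keeping rays already in the
hyperplane and combining positive/negative pairs that pass the
elementarity (support-adjacency) test.

For cross-network comparison an EFM is identified by its SUPPORT over
original reaction ids (coefficients are only defined up to positive
scaling); spurious two-cycles of split reversible pairs are removed
and forward/backward columns folded together.

`brute_force_efms` is an independent oracle — LP feasibility over all
reaction subsets — used to certify completeness and soundness on small
networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, SplitMap

#: Steady-state tolerance for accepting a ray (after max-normalisation).
CONSERVATION_TOL = 1e-9


class EFMResourceError(RuntimeError):
    """Raised when enumeration would exceed the configured ray budget."""


@dataclass(frozen=True)
class EFM:
    """One elementary mode: original-id support + normalised coefficients."""

    support: frozenset[str]
    coefficients: tuple[tuple[str, float], ...]  # column id -> coefficient, max = 1


@dataclass
class EFMSet:
    """The EFMs of one network, keyed by support signatures."""

    network_id: tuple | str | None
    efms: list[EFM] = field(default_factory=list)

    @property
    def supports(self) -> frozenset[frozenset[str]]:
        return frozenset(e.support for e in self.efms)

    def __len__(self) -> int:
        return len(self.efms)


def _spurious_two_cycle(cols: frozenset[str], split: SplitMap) -> bool:
    if len(cols) != 2:
        return False
    for fwd, bwd in split.pairs.values():
        if cols == frozenset((fwd, bwd)):
            return True
    return False


def _finalize(rays, model, split, network_id) -> EFMSet:
    """Normalise, drop split two-cycles, fold to original ids, dedupe."""
    seen: dict[frozenset[str], EFM] = {}
    for r in rays:
        r = np.asarray(r, float)
        mx = r.max()
        if mx <= 0:
            continue
        r = r / mx
        r[r < CONSERVATION_TOL] = 0.0
        cols = frozenset(
            model.reactions[j] for j in np.flatnonzero(r)
        )
        if not cols or _spurious_two_cycle(cols, split):
            continue
        support = split.fold_support(cols)
        if support in seen:
            continue
        coeffs = tuple(
            (model.reactions[j], float(r[j])) for j in np.flatnonzero(r)
        )
        seen[support] = EFM(support=support, coefficients=coeffs)
    return EFMSet(network_id=network_id, efms=list(seen.values()))


def enumerate_efms(
    model: MetabolicModel,
    split: SplitMap | None = None,
    network_id=None,
    max_rays: int = 200_000,
) -> EFMSet:
    """All EFMs of an irreversible model by double description.

    Parameters
    ----------
    model : irreversible model (all lower bounds zero)
    split : bookkeeping from :func:`adam.model.to_irreversible`; used to
        drop spurious forward/backward two-cycles and to fold supports
        back to original reaction ids.
    max_rays : abort (``EFMResourceError``) if the intermediate ray set
        exceeds this budget — never a silent truncation.
    """
    if np.any(model.lower < 0):
        raise ValueError("EFM enumeration requires the irreversible form")
    split = split or SplitMap(pairs={})
    n = model.n_reactions
    S = model.S.toarray()

    rays = list(np.eye(n))
    # process metabolites in ascending order of candidate pair count
    remaining = list(range(model.n_metabolites))
    while remaining:
        scores = []
        for i in remaining:
            t = np.array([S[i] @ r for r in rays])
            scores.append((int((t > 0).sum()) * int((t < 0).sum()), i))
        scores.sort()
        _, i = scores[0]
        remaining.remove(i)

        t = np.array([S[i] @ r for r in rays])
        zero = [r for r, ti in zip(rays, t) if abs(ti) <= 1e-12]
        pos = [(r, ti) for r, ti in zip(rays, t) if ti > 1e-12]
        neg = [(r, ti) for r, ti in zip(rays, t) if ti < -1e-12]

        supports = [frozenset(np.flatnonzero(r > 1e-12)) for r in rays]
        new = list(zero)
        for (rp, tp), (rq, tq) in itertools.product(pos, neg):
            sp_ = frozenset(np.flatnonzero(rp > 1e-12))
            sq_ = frozenset(np.flatnonzero(rq > 1e-12))
            union = sp_ | sq_
            # adjacency: no third ray's support fits inside the union
            adjacent = True
            for s in supports:
                if s is sp_ or s is sq_:
                    continue
                if s <= union and s != sp_ and s != sq_:
                    adjacent = False
                    break
            if not adjacent:
                continue
            comb = (-tq) * rp + tp * rq
            comb[comb < 0] = 0.0  # clip round-off
            new.append(comb / comb.max())
            if len(new) > max_rays:
                raise EFMResourceError(
                    f"ray budget {max_rays} exceeded while processing metabolite "
                    f"{model.metabolites[i]}"
                )
        rays = new

    # final support-minimality sweep (guards against numerically kept rays)
    rays = [r for r in rays if np.abs(S @ r).max() <= 1e-7 * max(1.0, r.max())]
    supports = [frozenset(np.flatnonzero(np.asarray(r) / max(r.max(), 1e-300) > CONSERVATION_TOL)) for r in rays]
    keep = []
    for k, s in enumerate(supports):
        if not s:
            continue
        minimal = True
        for k2, s2 in enumerate(supports):
            if k2 != k and s2 and s2 < s:
                minimal = False
                break
        if minimal:
            keep.append(rays[k])
    return _finalize(keep, model, split, network_id)


def subnetwork(model: MetabolicModel, split: SplitMap, included: set[str]):
    """Restrict an irreversible model to the columns of included ORIGINAL ids."""
    cols = [
        j
        for j, col in enumerate(model.reactions)
        if split.original_id(col) in included
    ]
    sub = MetabolicModel(
        metabolites=list(model.metabolites),
        reactions=[model.reactions[j] for j in cols],
        S=model.S[:, cols],
        lower=model.lower[cols],
        upper=model.upper[cols],
        reversible=model.reversible[cols],
        objective=model.objective[cols],
        gpr={},
    )
    return sub


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_efms(
    model: MetabolicModel,
    split: SplitMap | None = None,
    network_id=None,
    max_reactions: int = 15,
) -> EFMSet:
    """EFMs by exhaustive subset enumeration + LP positivity (test oracle).

    A column subset T is an EFM support iff there exists v with
    S_T v = 0 and v_j >= 1 on T (scale-invariant strict positivity) and
    no proper subset of T is itself feasible.  Subsets are visited in
    increasing cardinality so minimality reduces to "contains no
    previously found support".  Refuses models beyond ``max_reactions``.
    """
    split = split or SplitMap(pairs={})
    n = model.n_reactions
    if n > max_reactions:
        raise ValueError(f"{n} reactions exceed brute-force guard {max_reactions}")
    S = model.S.toarray()
    pair_cols = [
        (model.reactions.index(f), model.reactions.index(b))
        for f, b in split.pairs.values()
        if f in model.reactions and b in model.reactions
    ]

    found_masks: list[int] = []
    found_rays: list[np.ndarray] = []
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            mask = 0
            for j in combo:
                mask |= 1 << j
            if any((mask >> f) & 1 and (mask >> b) & 1 for f, b in pair_cols):
                continue
            if any((m & mask) == m for m in found_masks):
                continue  # proper superset of a known EFM
            cols = list(combo)
            sub = S[:, cols]
            # necessary condition: every touched metabolite must balance
            touched = np.flatnonzero(np.abs(sub).sum(axis=1))
            if any(
                (sub[i] > 0).sum() == 0 or (sub[i] < 0).sum() == 0
                for i in touched
            ):
                continue
            res = linprog(
                c=np.zeros(size),
                A_eq=sub,
                b_eq=np.zeros(S.shape[0]),
                bounds=[(1.0, None)] * size,
                method="highs",
            )
            if res.status == 0:
                found_masks.append(mask)
                ray = np.zeros(n)
                ray[cols] = res.x
                found_rays.append(ray / ray.max())
    return _finalize(found_rays, model, split, network_id)


def compare_efm_sets(a: EFMSet, b: EFMSet) -> float:
    """Jaccard index of the two support-signature sets (both empty -> 1)."""
    sa, sb = a.supports, b.supports
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
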