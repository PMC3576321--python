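"""Bilevel network extraction: structure, duality, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from adam.fba import InfeasibleError, classify_dispensable
from adam.minnet import (
    brute_force_minimal_network,
    build_bilevel,
    dualize,
    extract_minimal_network,
    run_time_series,
    solve_inner_lp,
)
from adam.model import to_irreversible
from adam.synthetic import generate_model, oracle_scenario, random_weights

from conftest import build_model


def _setup(model, weights=None, f_min_fraction=0.10, threshold=0.99):
    split_model, split = to_irreversible(model)
    part = classify_dispensable(model, threshold)
    if weights is None:
        weights = pd.Series(1.0, index=model.reactions)
    spec = build_bilevel(split_model, split, weights, part, f_min_fraction)
    return spec, part


class TestBuild:
    def test_no_dispensables_degenerates_to_lp(self, chain_model):
        spec, part = _setup(chain_model)
        assert part.dispensable == []
        assert spec.dispensable == []
        milp = dualize(spec)
        assert milp.n_y == 0
        net = extract_minimal_network(milp)
        assert set(net.included) == set(chain_model.reactions)

    def test_zero_floor_makes_biomass_row_vacuous(self, diamond_model):
        w = pd.Series(-1.0, index=diamond_model.reactions)
        spec, _ = _setup(diamond_model, weights=w, f_min_fraction=0.0)
        status, v, obj = solve_inner_lp(spec, {"R1": 0, "R2": 0})
        assert status == "optimal"  # no biomass path needed at floor 0
        assert obj == pytest.approx(0.0, abs=1e-9)

    def test_structural_audit_variable_and_constraint_counts(self, diamond_model):
        """Hand count on the diamond: n=4 columns + EX_A split = 5,
        d=2 Booleans, m=2 metabolites, nd=2 dispensable columns."""
        spec, _ = _setup(diamond_model)
        milp = dualize(spec)
        n, m, d, nd = 5, 2, 2, 2
        assert milp.n_v == n and milp.n_y == d
        assert len(milp.var_lower) == n + d + m + 1 + n + nd
        total_rows = sum(c.A.shape[0] for c in milp.constraints)
        # Sv=0 (m) + floor (1) + v<=uy (nd) + dual feas (n) + duality (1)
        # + 3 linearization blocks (3*nd)
        assert total_rows == m + 1 + nd + n + 1 + 3 * nd

    def test_infinite_bound_requires_cap(self, diamond_model):
        model = diamond_model.copy()
        model.upper[model.reaction_index("R1")] = np.inf
        split_model, split = to_irreversible(model)
        part = classify_dispensable(diamond_model, 0.99)
        w = pd.Series(1.0, index=model.reactions)
        with pytest.raises(ValueError, match="bound_cap"):
            build_bilevel(split_model, split, w, part, 0.1)
        spec = build_bilevel(split_model, split, w, part, 0.1, bound_cap=1000.0)
        assert np.isfinite(spec.model.upper).all()


class TestDuality:
    def test_fixed_y_matches_direct_inner_lp(self, default_bundle):
        """The MILP's inner optimum at the chosen y equals a fresh LP
        solve (this is exactly what strong duality must enforce)."""
        _, model, _ = default_bundle
        spec, _ = _setup(model, random_weights(model, 5))
        net = extract_minimal_network(dualize(spec))
        y = {rid: int(rid in net.included_set) for rid in spec.dispensable}
        _, _, inner = solve_inner_lp(spec, y)
        assert net.inner_objective == pytest.approx(inner, rel=1e-6, abs=1e-6)

    def test_default_big_m_is_valid_and_small_m_is_not(self, default_bundle):
        """A deliberately tiny dual box changes/invalidates the optimum;
        the default box reproduces the exhaustive-oracle solution."""
        _, model, _ = default_bundle
        w = random_weights(model, 9)
        spec, _ = _setup(model, w)
        oracle = brute_force_minimal_network(spec)
        good = extract_minimal_network(dualize(spec))
        assert good.n_reactions == oracle.n_reactions
        assert good.inner_objective == pytest.approx(
            oracle.inner_objective, rel=1e-6, abs=1e-6
        )
        tiny = dualize(spec, big_m=1e-4)
        try:
            bad = extract_minimal_network(tiny)
            mismatch = bad.n_reactions != oracle.n_reactions or abs(
                bad.inner_objective - oracle.inner_objective
            ) > 1e-4 * (1 + abs(oracle.inner_objective))
        except (RuntimeError, InfeasibleError):
            mismatch = True  # truncated duals make the program infeasible/invalid
        assert mismatch


class TestExtraction:
    def test_nothing_removable_returns_full_network(self, chain_model):
        spec, _ = _setup(chain_model)
        net = extract_minimal_network(dualize(spec))
        assert net.n_reactions == chain_model.n_reactions

    def test_negatively_weighted_parallel_path_excluded(self, diamond_model):
        w = pd.Series(
            {"EX_A": 1.0, "R1": 2.0, "R2": -2.0, "BIOMASS": 1.0}
        )
        spec, _ = _setup(diamond_model, w)
        net = extract_minimal_network(dualize(spec))
        assert "R1" in net.included_set
        assert "R2" not in net.included_set
        assert abs(net.fluxes["R2"]) <= 1e-9

    def test_excluded_reactions_carry_zero_flux(self, default_bundle):
        _, model, _ = default_bundle
        spec, _ = _setup(model, random_weights(model, 21))
        net = extract_minimal_network(dualize(spec))
        for rid in set(model.reactions) - net.included_set:
            assert abs(net.fluxes[rid]) <= 1e-9

    def test_biomass_floor_met(self, default_bundle):
        _, model, _ = default_bundle
        spec, _ = _setup(model, random_weights(model, 22), f_min_fraction=0.2)
        net = extract_minimal_network(dualize(spec))
        assert net.biomass >= spec.f_min - 1e-6

    def test_infeasible_floor_reported(self, diamond_model):
        model = diamond_model.copy()
        model.upper[model.reaction_index("BIOMASS")] = 5.0
        split_model, split = to_irreversible(model)
        part = classify_dispensable(model, 0.99)
        w = pd.Series(1.0, index=model.reactions)
        spec = build_bilevel(split_model, split, w, part, 1.0)
        spec = type(spec)(**{**spec.__dict__, "f_min": spec.f_max * 2})
        with pytest.raises(InfeasibleError, match="f_min"):
            extract_minimal_network(dualize(spec))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        """Core property: (count, inner objective) equals brute force
        over all Boolean assignments on oracle-sized fixtures."""
        model, _ = generate_model(oracle_scenario(seed))
        spec, _ = _setup(model, random_weights(model, seed + 100))
        net = extract_minimal_network(dualize(spec))
        oracle = brute_force_minimal_network(spec)
        assert net.n_reactions == oracle.n_reactions
        assert net.inner_objective == pytest.approx(
            oracle.inner_objective, rel=1e-6, abs=1e-6
        )

    def test_f_min_monotonicity(self, default_bundle):
        """Raising the biomass floor never shrinks the minimal network."""
        _, model, _ = default_bundle
        w = random_weights(model, 31)
        counts = []
        for fmf in (0.01, 0.10, 0.20, 0.90):
            spec, _ = _setup(model, w, f_min_fraction=fmf)
            counts.append(extract_minimal_network(dualize(spec)).n_reactions)
        assert counts == sorted(counts)


class TestTimeSeries:
    def _weights_frame(self, model, times, maker):
        rows = []
        for t in times:
            w = maker(t)
            for rid in model.reactions:
                rows.append(
                    {"reaction": rid, "condition": "c", "time_min": t,
                     "weight": w[rid]}
                )
        return pd.DataFrame(rows)

    def test_constant_weights_give_identical_networks(self, default_bundle):
        _, model, _ = default_bundle
        w = random_weights(model, 77)
        split_model, split = to_irreversible(model)
        part = classify_dispensable(model, 0.99)
        frame = self._weights_frame(model, [0.0, 10.0, 20.0], lambda t: w)
        nets = run_time_series(split_model, split, frame, part)
        assert len(nets) == 3
        sets = [n.included_set for n in nets.values()]
        assert sets[0] == sets[1] == sets[2]

    def test_one_network_per_key(self, default_bundle):
        _, model, _ = default_bundle
        split_model, split = to_irreversible(model)
        part = classify_dispensable(model, 0.99)
        rows = []
        for cond in ("cold", "heat"):
            for t in np.linspace(0, 90, 7):
                w = random_weights(model, int(t) + (0 if cond == "cold" else 1000))
                for rid in model.reactions:
                    rows.append(
                        {"reaction": rid, "condition": cond, "time_min": t,
                         "weight": w[rid]}
                    )
        nets = run_time_series(split_model, split, pd.DataFrame(rows), part)
        assert len(nets) == 14
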