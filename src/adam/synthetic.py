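"""Synthetic toy models and matched time-series expression data.

The generator emulates the data shape the pipeline consumes: a small
stoichiometric model with GPR rules, plus a bimodal expression time
series in which known reaction subsets are (de)activated at known time
points.  Its topology is a glucose-like uptake feeding a linear core
chain, a branch point with parallel paths of configurable yield that
reconverge, a tail to a biomass sink, and dispensable "decoration"
branches that secrete a by-product:

    uptake -> C0 -> ... -> branch ==(paths)== Q -> ... -> biomass
                        \\-> W_k -> (secreted)

The default activation schedule switches flux-carrying capability from
path 0 to path 1 at a known time: path-gene expression is drawn from
the active component N(active_mean, sd) or the inactive component
N(inactive_mean, sd), giving each switched gene a bimodal pooled
distribution; differential-expression p-values and directions are
generated directly (the pipeline's contract starts at the p-value
table).  Everything is a pure function of the scenario seed.

Fixture sizes are capped so the exhaustive bilevel and EFM oracles
apply; ``large`` scenarios exist for smoke tests only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gpr import parse_gpr
from .model import MediumSpec, MetabolicModel, save_model


class GenerationError(ValueError):
    """Raised for scenario parameters that cannot produce a viable model."""


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study; the seed fixes every output."""

    seed: int = 17
    n_core: int = 2  # reactions upstream of the branch point
    n_tail: int = 1  # reactions between reconvergence and biomass
    n_paths: int = 2  # parallel branch->Q paths, 2 reactions each
    path_yields: tuple = (1.0, 1.0)
    shortcut: bool = False  # extra 1-reaction branch->Q route
    shortcut_yield: float = 0.8
    n_decorations: int = 2  # dispensable secretion branches, 2 reactions each
    reversible_decoration: bool = True  # first decoration internal step reversible
    uptake_bound: float = 10.0
    default_bound: float = 1000.0
    times: tuple = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0)
    conditions: tuple = ("stress",)
    switch_time: float = 30.0  # path 1 takes over at t >= switch_time
    active_mean: float = 8.0
    inactive_mean: float = 2.0
    noise_sd: float = 0.25
    de_p_significant: float = 1e-4
    de_p_null: float = 0.9

    def __post_init__(self):
        if self.n_paths < 1 or len(self.path_yields) != self.n_paths:
            raise GenerationError("path_yields must list one yield per path")
        if self.active_mean <= self.inactive_mean:
            raise GenerationError("active_mean must exceed inactive_mean")
        if list(self.times) != sorted(set(self.times)):
            raise GenerationError("times must be strictly increasing")


@dataclass
class GroundTruth:
    """What the generator intended, for end-to-end verification."""

    active_reactions: dict[tuple[str, float], frozenset[str]]
    intended_class: dict[str, str]  # reaction -> flat | fluctuating
    gene_states: pd.DataFrame  # gene, condition, time_min, active
    core_reactions: list[str]
    path_reactions: dict[int, list[str]]
    decoration_reactions: list[str]
    switch_time: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "active_reactions": {
                    f"{c}|{t}": sorted(v)
                    for (c, t), v in self.active_reactions.items()
                },
                "intended_class": self.intended_class,
                "gene_states": self.gene_states.to_dict(orient="list"),
                "core_reactions": self.core_reactions,
                "path_reactions": {str(k): v for k, v in self.path_reactions.items()},
                "decoration_reactions": self.decoration_reactions,
                "switch_time": self.switch_time,
            },
            indent=1,
            sort_keys=True,
        )


def _path_active(scenario: SyntheticScenario, k: int, t: float) -> bool:
    if k == 0:
        return t < scenario.switch_time
    if k == 1 and scenario.n_paths > 1:
        return t >= scenario.switch_time
    return False


def generate_model(
    scenario: SyntheticScenario,
) -> tuple[MetabolicModel, GroundTruth]:
    """Build the toy model and its ground truth from a scenario."""
    mets: list[str] = []
    rxn_rows: list[dict] = []  # id, stoich {met: coeff}, lb, ub, obj, gpr

    def met(name):
        if name not in mets:
            mets.append(name)
        return name

    def rxn(rid, stoich, lb, ub, obj=0.0, gpr=""):
        rxn_rows.append(
            {"id": rid, "stoich": stoich, "lb": lb, "ub": ub, "obj": obj, "gpr": gpr}
        )

    core_ids, tail_ids = [], []
    path_ids: dict[int, list[str]] = {}
    dec_ids: list[str] = []

    rxn("EX_glc", {met("C0"): -1.0}, -scenario.uptake_bound, 0.0)
    prev = "C0"
    for i in range(1, scenario.n_core + 1):
        rid = f"R_core{i}"
        rxn(rid, {prev: -1.0, met(f"C{i}"): 1.0}, 0.0, scenario.default_bound,
            gpr=f"g_core{i}")
        core_ids.append(rid)
        prev = f"C{i}"
    branch = prev

    met("Q")
    for k in range(scenario.n_paths):
        a, b = f"R_path{k}a", f"R_path{k}b"
        rxn(a, {branch: -1.0, met(f"P{k}"): 1.0}, 0.0, scenario.default_bound,
            gpr=f"g_p{k}a1 and g_p{k}a2")
        rxn(b, {f"P{k}": -1.0, "Q": scenario.path_yields[k]}, 0.0,
            scenario.default_bound, gpr=f"g_p{k}b")
        path_ids[k] = [a, b]
    if scenario.shortcut:
        rxn("R_short", {branch: -1.0, "Q": scenario.shortcut_yield}, 0.0,
            scenario.default_bound, gpr="g_short")

    prev = "Q"
    for i in range(1, scenario.n_tail + 1):
        rid = f"R_tail{i}"
        rxn(rid, {prev: -1.0, met(f"T{i}"): 1.0}, 0.0, scenario.default_bound,
            gpr=f"g_tail{i}")
        tail_ids.append(rid)
        prev = f"T{i}"
    rxn("BIOMASS", {prev: -1.0}, 0.0, scenario.default_bound, obj=1.0)

    for k in range(scenario.n_decorations):
        rid, ex = f"R_dec{k}", f"EX_w{k}"
        lb = (
            -scenario.default_bound
            if (k == 0 and scenario.reversible_decoration)
            else 0.0
        )
        rxn(rid, {branch: -1.0, met(f"W{k}"): 1.0}, lb, scenario.default_bound,
            gpr=f"g_dec{k}")
        rxn(ex, {f"W{k}": -1.0}, 0.0, scenario.default_bound)
        dec_ids += [rid, ex]

    met_idx = {m: i for i, m in enumerate(mets)}
    rows, cols, vals = [], [], []
    for j, r in enumerate(rxn_rows):
        for m, coeff in r["stoich"].items():
            rows.append(met_idx[m])
            cols.append(j)
            vals.append(coeff)
    model = MetabolicModel(
        metabolites=mets,
        reactions=[r["id"] for r in rxn_rows],
        S=sp.csc_matrix((vals, (rows, cols)), shape=(len(mets), len(rxn_rows))),
        lower=np.array([r["lb"] for r in rxn_rows]),
        upper=np.array([r["ub"] for r in rxn_rows]),
        reversible=np.array([r["lb"] < 0 for r in rxn_rows]),
        objective=np.array([r["obj"] for r in rxn_rows]),
        gpr={r["id"]: parse_gpr(r["gpr"]) for r in rxn_rows if r["gpr"]},
    )
    model.validate()

    from .fba import flux_balance

    if not flux_balance(model).optimal or flux_balance(model).objective <= 0:
        raise GenerationError("scenario produced a model with zero biomass")

    backbone = ["EX_glc", *core_ids, *tail_ids, "BIOMASS"]
    active: dict[tuple[str, float], frozenset[str]] = {}
    for cond in scenario.conditions:
        for t in scenario.times:
            on = set(backbone)
            for k in range(scenario.n_paths):
                if _path_active(scenario, k, t):
                    on |= set(path_ids[k])
            active[(cond, t)] = frozenset(on)

    union: set[str] = set().union(*active.values())
    intended = {}
    for rid in union:
        ever_off = any(rid not in s for s in active.values())
        intended[rid] = "fluctuating" if ever_off else "flat"

    gene_rows = []
    gene_of: dict[str, list[str]] = {}
    for r in rxn_rows:
        if r["gpr"]:
            from .gpr import gpr_genes

            gene_of[r["id"]] = sorted(gpr_genes(model.gpr[r["id"]]))
    for cond in scenario.conditions:
        for t in scenario.times:
            for rid, genes in gene_of.items():
                is_on = rid in active[(cond, t)]
                for g in genes:
                    gene_rows.append(
                        {"gene": g, "condition": cond, "time_min": t, "active": is_on}
                    )
    gene_states = (
        pd.DataFrame(gene_rows)
        .drop_duplicates(["gene", "condition", "time_min"])
        .reset_index(drop=True)
    )

    truth = GroundTruth(
        active_reactions=active,
        intended_class=intended,
        gene_states=gene_states,
        core_reactions=backbone,
        path_reactions=path_ids,
        decoration_reactions=dec_ids,
        switch_time=scenario.switch_time,
    )
    return model, truth


def generate_expression(
    scenario: SyntheticScenario, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression and differential tables matching the ground truth.

    Expression: active genes draw from N(active_mean, sd), inactive
    from N(inactive_mean, sd).  Differential rows compare each gene's
    state to its state at the first time point: a changed state gets
    the significant p-value and the corresponding direction.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    t0 = scenario.times[0]
    base_state = {
        (r.gene, r.condition): r.active
        for r in truth.gene_states.itertuples()
        if r.time_min == t0
    }
    expr_rows, de_rows = [], []
    for r in truth.gene_states.itertuples():
        mean = scenario.active_mean if r.active else scenario.inactive_mean
        value = mean + (rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd > 0 else 0.0)
        expr_rows.append(
            {"gene": r.gene, "condition": r.condition, "time_min": r.time_min,
             "value": value}
        )
        changed = r.active != base_state[(r.gene, r.condition)]
        de_rows.append(
            {
                "gene": r.gene,
                "condition": r.condition,
                "time_min": r.time_min,
                "p_value": scenario.de_p_significant if changed else scenario.de_p_null,
                "direction": ("up" if r.active else "down") if changed else "none",
            }
        )
    return pd.DataFrame(expr_rows), pd.DataFrame(de_rows)


def default_medium(scenario: SyntheticScenario) -> MediumSpec:
    """Only the carbon uptake is open; by-product secretion stays free."""
    return MediumSpec({"EX_glc": (-scenario.uptake_bound, 0.0)})


def end_to_end_fixture(
    scenario: SyntheticScenario, outdir: str | Path
) -> dict[str, Path]:
    """Write model, medium, expression, DE and ground truth to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    model, truth = generate_model(scenario)
    expr, de = generate_expression(scenario, truth)

    model_dir = out / "model"
    save_model(model, model_dir)
    default_medium(scenario).to_tsv(out / "medium.tsv")
    expr.to_csv(out / "expression.tsv", sep="\t", index=False)
    de.to_csv(out / "differential.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(truth.to_json())
    manifest = {
        "scenario": dataclasses.asdict(scenario),
        "files": [
            "model/reactions.tsv", "model/metabolites.tsv",
            "model/stoichiometry.tsv", "medium.tsv", "expression.tsv",
            "differential.tsv", "ground_truth.json",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "model": model_dir,
        "medium": out / "medium.tsv",
        "expression": out / "expression.tsv",
        "differential": out / "differential.tsv",
        "ground_truth": out / "ground_truth.json",
    }


# ---------------------------------------------------------------------------
# Randomised fixture families for the exhaustive oracles
# ---------------------------------------------------------------------------

def oracle_scenario(seed: int) -> SyntheticScenario:
    """A randomised small scenario whose Boolean count stays oracle-sized.

    Topology parameters are drawn from the seed under the constraint
    that the number of dispensable reactions is <= 10 and the number of
    split columns stays brute-force enumerable.
    """
    rng = np.random.default_rng(seed)
    n_paths = int(rng.integers(2, 4))  # 2 or 3
    max_dec = 2 if n_paths == 3 else 3
    shortcut = bool(rng.integers(0, 2)) and n_paths == 2
    n_dec = int(rng.integers(0, max_dec))
    yields = tuple(np.round(rng.uniform(0.7, 1.0, size=n_paths), 3))
    return SyntheticScenario(
        seed=seed,
        n_core=int(rng.integers(1, 3)),
        n_tail=1,
        n_paths=n_paths,
        path_yields=yields,
        shortcut=shortcut,
        shortcut_yield=float(np.round(rng.uniform(0.6, 0.95), 3)),
        n_decorations=n_dec,
        reversible_decoration=bool(rng.integers(0, 2)),
    )


def efm_oracle_scenario(seed: int) -> SyntheticScenario:
    """A randomised scenario small enough for exhaustive EFM enumeration.

    Keeps the irreversible split form at <= 12 columns so the
    subset-enumeration oracle stays cheap.
    """
    rng = np.random.default_rng(seed)
    n_dec = int(rng.integers(0, 2))
    return SyntheticScenario(
        seed=seed,
        n_core=1 if n_dec else int(rng.integers(1, 3)),
        n_tail=1,
        n_paths=2,
        path_yields=tuple(np.round(rng.uniform(0.7, 1.0, size=2), 3)),
        shortcut=bool(rng.integers(0, 2)) and n_dec == 0,
        shortcut_yield=float(np.round(rng.uniform(0.6, 0.95), 3)),
        n_decorations=n_dec,
        reversible_decoration=bool(rng.integers(0, 2)),
    )


def random_weights(model: MetabolicModel, seed: int, scale: float = 2.0) -> pd.Series:
    """Gaussian reaction weights for oracle fixtures (bypasses expression)."""
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(0.0, scale, size=model.n_reactions),
                     index=model.reactions)
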