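"""Full-run orchestration: weights -> partition -> extraction -> EFMs -> profiles.

Each (condition, time point) is processed independently; the temporal
dependency lives in the expression data, not in the programs.  Every
stage writes a re-loadable table so a run can be resumed from any
completed stage, and a JSON run log records parameters, seeds, solver
statuses and logged decision events.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .efm import EFMSet, enumerate_efms, subnetwork
from .fba import DispensabilityPartition, classify_dispensable, flux_balance
from .minnet import MinimalNetwork, run_time_series
from .model import MediumSpec, apply_medium, load_model, to_irreversible
from .profiles import (
    classify_profiles,
    cluster_profiles,
    fractional_appearance,
    select_top_reactions,
    transition_summary,
)
from .weighting import build_gene_weight_table, map_weights_to_reactions

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one full run."""

    model_path: str | Path
    expression_path: str | Path
    differential_path: str | Path
    out_dir: str | Path
    medium_path: str | Path | None = None
    model_format: str = "tsv"
    alpha: float = 0.05
    f_min_fraction: float = 0.10
    dispensability_threshold: float = 0.99
    top_n: int = 50
    k_clusters: int = 9
    cluster_method: str = "hierarchical"
    seed: int = 0
    bound_cap: float | None = None
    big_m: float | None = None
    resume: bool = False

    def validate_paths(self) -> None:
        for name in ("model_path", "expression_path", "differential_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        if self.medium_path is not None and not Path(self.medium_path).exists():
            raise FileNotFoundError(f"medium_path does not exist: {self.medium_path}")


@dataclass
class ConditionResult:
    condition: str
    times: list[float]
    profile: pd.DataFrame
    transitions: object
    classification: pd.DataFrame
    clusters: object
    selected: list[str]


@dataclass
class RunResult:
    config: RunConfig
    gene_weights: pd.DataFrame
    reaction_weights: pd.DataFrame
    partition: DispensabilityPartition
    networks: dict[tuple[str, float], MinimalNetwork]
    efm_sets: dict[tuple[str, float], EFMSet]
    by_condition: dict[str, ConditionResult]
    log: dict = field(default_factory=dict)


def run_adam(config: RunConfig) -> RunResult:
    """Execute the whole pipeline and write all stage outputs."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events: list[str] = []

    # -- stage 1: inputs -------------------------------------------------
    model = load_model(config.model_path, format=config.model_format)
    if config.medium_path is not None:
        model = apply_medium(model, MediumSpec.from_tsv(config.medium_path))
    expression = pd.read_csv(config.expression_path, sep="\t")
    differential = pd.read_csv(config.differential_path, sep="\t")

    # -- stage 2: weights ------------------------------------------------
    weights_path = out / "reaction_weights.tsv"
    gene_weights_path = out / "gene_weights.tsv"
    if config.resume and weights_path.exists() and gene_weights_path.exists():
        events.append("resumed: reaction weights loaded from previous run")
        gene_weights = pd.read_csv(gene_weights_path, sep="\t")
        reaction_weights = pd.read_csv(weights_path, sep="\t")
    else:
        gene_weights = build_gene_weight_table(
            expression, differential, alpha=config.alpha, seed=config.seed
        )
        reaction_weights = map_weights_to_reactions(model, gene_weights)
        gene_weights.to_csv(gene_weights_path, sep="\t", index=False)
        reaction_weights.to_csv(weights_path, sep="\t", index=False)
    coverage = (
        reaction_weights.groupby("provenance")["reaction"].count()
        / len(reaction_weights)
    ).to_dict()
    events.append(f"weight provenance fractions: {coverage}")

    # -- stage 3: dispensability partition --------------------------------
    partition_path = out / "partition.tsv"
    if config.resume and partition_path.exists():
        events.append("resumed: partition loaded from previous run")
        f_max = flux_balance(model).objective
        partition = DispensabilityPartition.from_frame(
            pd.read_csv(partition_path, sep="\t"),
            config.dispensability_threshold,
            f_max,
        )
    else:
        partition = classify_dispensable(model, config.dispensability_threshold)
        partition.to_frame().to_csv(partition_path, sep="\t", index=False)
    events.append(
        f"partition: {len(partition.dispensable)} dispensable / "
        f"{len(partition.indispensable)} indispensable, f_max={partition.f_max:g}"
    )

    # -- stage 4: minimal networks ----------------------------------------
    split_model, split = to_irreversible(model)
    networks = run_time_series(
        split_model,
        split,
        reaction_weights,
        partition,
        f_min_fraction=config.f_min_fraction,
        bound_cap=config.bound_cap,
        big_m=config.big_m,
    )
    expected = reaction_weights[["condition", "time_min"]].drop_duplicates()
    if len(networks) < len(expected):
        missing = len(expected) - len(networks)
        events.append(f"WARNING: {missing} extractions failed; see log")
    net_rows = []
    for (cond, t), net in sorted(networks.items()):
        for rid in model.reactions:
            net_rows.append(
                {
                    "condition": cond,
                    "time_min": t,
                    "reaction": rid,
                    "included": int(rid in net.included_set),
                    "flux": float(net.fluxes.get(rid, 0.0)),
                }
            )
    pd.DataFrame(net_rows).to_csv(out / "networks.tsv", sep="\t", index=False)
    meta = {
        f"{cond}|{t}": {
            "n_reactions": net.n_reactions,
            "biomass": net.biomass,
            "inner_objective": net.inner_objective,
            "status": net.status,
            "f_min": net.f_min,
            "two_cycles": net.two_cycles,
        }
        for (cond, t), net in sorted(networks.items())
    }
    (out / "networks.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    # -- stage 5: EFM enumeration -----------------------------------------
    efm_sets: dict[tuple[str, float], EFMSet] = {}
    efm_rows = []
    for (cond, t), net in sorted(networks.items()):
        es = enumerate_efms(
            subnetwork(split_model, split, net.included_set),
            split,
            network_id=(cond, t),
        )
        efm_sets[(cond, t)] = es
        for e in es.efms:
            efm_rows.append(
                {
                    "condition": cond,
                    "time_min": t,
                    "support_size": len(e.support),
                    "support": ";".join(sorted(e.support)),
                }
            )
    pd.DataFrame(efm_rows).to_csv(out / "efms.tsv", sep="\t", index=False)

    # -- stage 6: per-condition analytics ----------------------------------
    by_condition: dict[str, ConditionResult] = {}
    conditions = sorted({c for c, _ in networks})
    for cond in conditions:
        times = sorted(t for c, t in networks if c == cond)
        sets = [efm_sets[(cond, t)] for t in times]
        nets = [networks[(cond, t)] for t in times]
        universe = sorted(set().union(*(n.included_set for n in nets)))
        profile = fractional_appearance(sets, times, reactions=universe)
        profile.to_csv(out / f"profile_{cond}.tsv", sep="\t")

        trans = transition_summary(sets, nets, times, partition, all_pairs=True)
        trans.consecutive.to_csv(
            out / f"transitions_{cond}.tsv", sep="\t", index=False
        )

        classification = classify_profiles(profile)
        selected = select_top_reactions(profile, n=config.top_n)
        k_eff = min(config.k_clusters, len(selected))
        if k_eff < config.k_clusters:
            events.append(
                f"{cond}: only {len(selected)} selected reactions; k reduced to {k_eff}"
            )
        clusters = cluster_profiles(
            profile, selected, k=k_eff, seed=config.seed,
            method=config.cluster_method,
        )
        cluster_df = pd.DataFrame(
            {
                "reaction": clusters.reactions,
                "cluster": clusters.assignment.to_numpy(),
                "class": classification.loc[clusters.reactions, "class"].to_numpy(),
            }
        )
        cluster_df.to_csv(out / f"clusters_{cond}.tsv", sep="\t", index=False)
        by_condition[cond] = ConditionResult(
            condition=cond,
            times=times,
            profile=profile,
            transitions=trans,
            classification=classification,
            clusters=clusters,
            selected=selected,
        )

    # -- stage 7: run log ---------------------------------------------------
    log = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "solver_status": {
            f"{c}|{t}": net.status for (c, t), net in sorted(networks.items())
        },
        "events": events,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))

    return RunResult(
        config=config,
        gene_weights=gene_weights,
        reaction_weights=reaction_weights,
        partition=partition,
        networks=networks,
        efm_sets=efm_sets,
        by_condition=by_condition,
        log=log,
    )
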