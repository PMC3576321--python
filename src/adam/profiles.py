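"""Time-resolved analytics over minimal networks and their EFM sets.

The central object is the fractional-appearance profile

    X(i, j) = (# EFMs at time j whose support contains reaction i)
              / (total # EFMs at time j)

a time-resolved measure of a reaction's contribution to network
functionality.  Profiles are classified as *flat* (X > 0 at every time
point; homeostasis-associated) or *fluctuating* (X = 0 at one or more
time points; adaptation-associated), compared across consecutive time
points with the Jaccard index, correlated with Kendall's tau and
clustered.  Robustness utilities perturb reaction weights and re-run
the extraction to measure the stability of the resulting networks and
EFM sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import kendalltau

from .efm import EFMSet, compare_efm_sets

logger = logging.getLogger(__name__)


def jaccard(a, b) -> float:
    """|a n b| / |a u b|; 1.0 for two empty sets by convention (logged)."""
    a, b = set(a), set(b)
    if not a and not b:
        logger.debug("jaccard of two empty sets -> 1.0 by convention")
        return 1.0
    return len(a & b) / len(a | b)


def fractional_appearance(
    efm_sets: list[EFMSet],
    times: list[float],
    reactions: list[str] | None = None,
) -> pd.DataFrame:
    """Reaction x time matrix of fractional appearances X(i, j).

    Parameters
    ----------
    efm_sets : one EFMSet per time point, aligned with ``times``; an
        empty set makes the ratio undefined and is an error.
    reactions : row universe; defaults to the union of all supports.
        Reactions absent from a time point's network have X = 0 there.
    """
    if len(efm_sets) != len(times):
        raise ValueError("efm_sets and times must align")
    for es, t in zip(efm_sets, times):
        if len(es) == 0:
            raise ValueError(f"empty EFM set at time {t}: X(i,j) undefined")
    if reactions is None:
        universe: set[str] = set()
        for es in efm_sets:
            for e in es.efms:
                universe |= e.support
        reactions = sorted(universe)

    X = np.zeros((len(reactions), len(times)))
    ridx = {r: i for i, r in enumerate(reactions)}
    for j, es in enumerate(efm_sets):
        total = len(es)
        for e in es.efms:
            for r in e.support:
                if r in ridx:
                    X[ridx[r], j] += 1.0
        X[:, j] /= total
    return pd.DataFrame(X, index=reactions, columns=times)


def select_top_reactions(profile: pd.DataFrame, n: int = 50) -> list[str]:
    """Union over time points of the n highest-X reactions per time point.

    Ties at the cutoff are broken by lexicographic reaction id (logged).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    selected: set[str] = set()
    for t in profile.columns:
        col = profile[t]
        order = sorted(zip(-col.to_numpy(), col.index))  # desc X, asc id
        cut = order[: min(n, len(order))]
        if len(order) > n and order[n - 1][0] == order[n][0]:
            logger.debug("top-%d tie at time %s broken lexicographically", n, t)
        selected |= {rid for _, rid in cut}
    return sorted(selected)


@dataclass
class TransitionSummary:
    """Jaccard similarities between time points."""

    consecutive: pd.DataFrame  # time_from, time_to, jaccard_efm, jaccard_dispensable
    all_pairs_efm: pd.DataFrame | None = None  # time x time matrices
    all_pairs_dispensable: pd.DataFrame | None = None


def transition_summary(
    efm_sets: list[EFMSet],
    networks: list,
    times: list[float],
    partition,
    all_pairs: bool = True,
) -> TransitionSummary:
    """Jaccard of consecutive (and all-pairs) EFM-support sets and of the
    dispensable reactions retained in the minimal networks."""
    disp = set(partition.dispensable)
    disp_sets = [set(net.included) & disp for net in networks]

    rows = []
    for k in range(len(times) - 1):
        rows.append(
            {
                "time_from": times[k],
                "time_to": times[k + 1],
                "jaccard_efm": compare_efm_sets(efm_sets[k], efm_sets[k + 1]),
                "jaccard_dispensable": jaccard(disp_sets[k], disp_sets[k + 1]),
            }
        )
    consecutive = pd.DataFrame(rows)

    ap_efm = ap_disp = None
    if all_pairs:
        T = len(times)
        ap_efm = pd.DataFrame(np.eye(T), index=times, columns=times)
        ap_disp = pd.DataFrame(np.eye(T), index=times, columns=times)
        for a in range(T):
            for b in range(a + 1, T):
                je = compare_efm_sets(efm_sets[a], efm_sets[b])
                jd = jaccard(disp_sets[a], disp_sets[b])
                ap_efm.iloc[a, b] = ap_efm.iloc[b, a] = je
                ap_disp.iloc[a, b] = ap_disp.iloc[b, a] = jd
    return TransitionSummary(
        consecutive=consecutive, all_pairs_efm=ap_efm, all_pairs_dispensable=ap_disp
    )


def kendall_matrix(profile: pd.DataFrame, reactions=None) -> pd.DataFrame:
    """Pairwise tie-corrected Kendall tau_b between reaction profiles.

    Zero-variance profiles have undefined correlation; those entries
    are NaN (missing), never coerced to 0.  Diagonal is 1.
    """
    if profile.shape[1] < 2:
        raise ValueError("need at least 2 time points for correlation")
    sub = profile.loc[list(reactions)] if reactions is not None else profile
    ids = list(sub.index)
    n = len(ids)
    tau = np.full((n, n), np.nan)
    values = sub.to_numpy()
    const = np.ptp(values, axis=1) == 0
    for a in range(n):
        tau[a, a] = 1.0
        for b in range(a + 1, n):
            if const[a] or const[b]:
                continue
            t, _ = kendalltau(values[a], values[b], variant="b")
            tau[a, b] = tau[b, a] = t
    return pd.DataFrame(tau, index=ids, columns=ids)


@dataclass
class ClusterResult:
    reactions: list[str]
    assignment: pd.Series  # reaction -> cluster label (1..k)
    k: int
    method: str
    seed: int | None
    tau: pd.DataFrame | None = None


def cluster_profiles(
    profile: pd.DataFrame,
    reactions=None,
    k: int = 9,
    seed: int = 0,
    method: str = "hierarchical",
) -> ClusterResult:
    """Cluster fractional-appearance profiles into k groups.

    Default: average-linkage hierarchical clustering on the 1 - tau_b
    distance (undefined tau treated as 0 correlation, i.e. distance 1,
    logged).  Alternative ``method="kmeans"`` clusters the raw profiles
    with a fixed seed.
    """
    sub = profile.loc[list(reactions)] if reactions is not None else profile
    ids = list(sub.index)
    if not (1 <= k <= len(ids)):
        raise ValueError(f"k={k} invalid for {len(ids)} reactions")

    tau = None
    if method == "hierarchical":
        tau = kendall_matrix(sub)
        dist = 1.0 - tau.to_numpy()
        if np.isnan(dist).any():
            logger.debug("undefined tau entries -> distance 1 for clustering")
            dist = np.where(np.isnan(dist), 1.0, dist)
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        labels = fcluster(
            linkage(squareform(dist, checks=False), method="average"),
            t=k,
            criterion="maxclust",
        )
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        labels = (
            KMeans(n_clusters=k, random_state=seed, n_init=10)
            .fit_predict(sub.to_numpy())
            + 1
        )
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return ClusterResult(
        reactions=ids,
        assignment=pd.Series(labels, index=ids),
        k=k,
        method=method,
        seed=seed,
        tau=tau,
    )


def classify_profiles(profile: pd.DataFrame) -> pd.DataFrame:
    """Flat (X > 0 everywhere) vs fluctuating (X = 0 at >= 1 time point)."""
    zero_mask = profile.to_numpy() <= 0.0
    fluctuating = zero_mask.any(axis=1)
    return pd.DataFrame(
        {
            "class": np.where(fluctuating, "fluctuating", "flat"),
            "n_zero_times": zero_mask.sum(axis=1),
        },
        index=profile.index,
    )


def perturb_weights(
    weights: pd.Series,
    n_reactions: int = 100,
    noise_fraction: float = 0.01,
    seed: int = 0,
) -> pd.Series:
    """Uniform noise on a random subset of reaction weights.

    The noise amplitude is ``noise_fraction`` of the total weight range
    (max - min); noise ~ U(-m, +m) is added to ``n_reactions``
    uniformly sampled reactions.  Deterministic per seed.
    """
    if n_reactions > len(weights):
        raise ValueError("n_reactions exceeds the number of reactions")
    if noise_fraction <= 0:
        raise ValueError("noise_fraction must be positive")
    rng = np.random.default_rng(seed)
    span = float(weights.max() - weights.min())
    if span <= 0:
        raise ValueError("degenerate weight range (max == min)")
    m = noise_fraction * span
    idx = rng.choice(len(weights), size=n_reactions, replace=False)
    out = weights.copy()
    out.iloc[idx] = out.iloc[idx] + rng.uniform(-m, m, size=n_reactions)
    return out


def overlap_smaller(a, b) -> float:
    """Reaction-set overlap as a percentage of the smaller set."""
    a, b = set(a), set(b)
    if not a or not b:
        return 100.0 if a == b else 0.0
    return 100.0 * len(a & b) / min(len(a), len(b))


@dataclass
class RobustnessReport:
    """Pairwise overlaps across a parameter grid and noise replicates."""

    grid_runs: pd.DataFrame  # threshold, f_min_fraction, n_reactions, ...
    pairwise: pd.DataFrame  # run_a, run_b, overlap_pct, jaccard_efm
    mean_overlap_pct: float
    mean_efm_jaccard: float
    noise_runs: pd.DataFrame | None = None
    mean_noise_efm_overlap_pct: float | None = None


def robustness_suite(
    model,
    weights: pd.Series,
    thresholds=(0.99, 0.95, 0.90),
    f_min_fractions=(0.01, 0.10, 0.20),
    noise_fraction: float = 0.01,
    n_noise_reactions: int | None = None,
    n_noise_repeats: int = 5,
    seed: int = 0,
) -> RobustnessReport:
    """Stability of extracted networks under parameter and weight noise.

    Re-runs the extraction on the ORIGINAL-form ``model`` across a
    dispensability-threshold x biomass-floor grid and under uniform
    noise (default 1% of the total weight range) on randomly selected
    reaction weights, then reports pairwise reaction-set overlaps
    (w.r.t. the smaller network) and EFM-set Jaccard/overlap values.
    Individual failures are logged and skipped; the suite continues.
    """
    from .efm import enumerate_efms, subnetwork
    from .fba import classify_dispensable
    from .minnet import build_bilevel, dualize, extract_minimal_network
    from .model import to_irreversible

    split_model, split = to_irreversible(model)
    efm_cache: dict[frozenset, EFMSet] = {}

    def efms_of(included: frozenset) -> EFMSet:
        if included not in efm_cache:
            efm_cache[included] = enumerate_efms(
                subnetwork(split_model, split, set(included)), split
            )
        return efm_cache[included]

    # --- parameter grid -------------------------------------------------
    runs = []
    partitions = {thr: classify_dispensable(model, thr) for thr in thresholds}
    for thr in thresholds:
        for fmf in f_min_fractions:
            try:
                spec = build_bilevel(
                    split_model, split, weights, partitions[thr], fmf
                )
                net = extract_minimal_network(dualize(spec))
                runs.append(
                    {
                        "threshold": thr,
                        "f_min_fraction": fmf,
                        "included": net.included_set,
                        "n_reactions": net.n_reactions,
                    }
                )
            except Exception as exc:  # noqa: BLE001
                logger.error("grid run (%s, %s) failed: %s", thr, fmf, exc)
    grid_runs = pd.DataFrame(runs)

    pairs = []
    for a in range(len(runs)):
        for b in range(a + 1, len(runs)):
            pairs.append(
                {
                    "run_a": a,
                    "run_b": b,
                    "overlap_pct": overlap_smaller(
                        runs[a]["included"], runs[b]["included"]
                    ),
                    "jaccard_efm": compare_efm_sets(
                        efms_of(runs[a]["included"]), efms_of(runs[b]["included"])
                    ),
                }
            )
    pairwise = pd.DataFrame(pairs)

    # --- weight noise ---------------------------------------------------
    n_noise = n_noise_reactions or min(100, len(weights))
    partition = partitions[thresholds[0]]
    base_fmf = f_min_fractions[1] if len(f_min_fractions) > 1 else f_min_fractions[0]
    spec = build_bilevel(split_model, split, weights, partition, base_fmf)
    base_net = extract_minimal_network(dualize(spec))
    base_efms = efms_of(base_net.included_set)
    noise_rows = []
    rng = np.random.default_rng(seed)
    for rep in range(n_noise_repeats):
        rep_seed = int(rng.integers(2**31))
        try:
            wn = perturb_weights(weights, n_noise, noise_fraction, seed=rep_seed)
            spec_n = build_bilevel(
                split_model, split, wn, partition, base_fmf
            )
            net_n = extract_minimal_network(dualize(spec_n))
            efms_n = efms_of(net_n.included_set)
            sa, sb = base_efms.supports, efms_n.supports
            efm_overlap = (
                100.0 * len(sa & sb) / min(len(sa), len(sb))
                if sa and sb
                else (100.0 if sa == sb else 0.0)
            )
            noise_rows.append(
                {
                    "repeat": rep,
                    "overlap_pct": overlap_smaller(
                        base_net.included_set, net_n.included_set
                    ),
                    "efm_overlap_pct": efm_overlap,
                    "jaccard_efm": compare_efm_sets(base_efms, efms_n),
                }
            )
        except Exception as exc:  # noqa: BLE001
            logger.error("noise repeat %d failed: %s", rep, exc)
    noise_runs = pd.DataFrame(noise_rows)

    return RobustnessReport(
        grid_runs=grid_runs,
        pairwise=pairwise,
        mean_overlap_pct=float(pairwise["overlap_pct"].mean()) if len(pairwise) else np.nan,
        mean_efm_jaccard=float(pairwise["jaccard_efm"].mean()) if len(pairwise) else np.nan,
        noise_runs=noise_runs,
        mean_noise_efm_overlap_pct=(
            float(noise_runs["efm_overlap_pct"].mean()) if len(noise_rows) else np.nan
        ),
    )
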