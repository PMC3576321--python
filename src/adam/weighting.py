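"""Expression-to-weight mapping.

Each gene at each (time point, condition) receives the weight

    w = I * z + (xi - theta) / theta

where ``xi`` is the expression value, ``theta`` a gene-specific
activation threshold, ``z`` the z-score of the differential-expression
p-value, and ``I`` a trivalued indicator (+1 up-regulated, -1
down-regulated, 0 no significant differential behaviour).  The first
term rewards significant differential expression in the direction of
change; the second rewards expression above the gene's active/inactive
threshold.

Thresholds come from a bimodality analysis: transiently (de)activated
genes show bimodal expression across conditions and time points, so a
two-component Gaussian mixture is fitted per gene; when it beats a
single Gaussian by BIC, the threshold is the equal-responsibility
boundary between the component means, otherwise the gene's median
expression is used.

Gene weights map to reaction weights through GPR rules (AND -> min,
OR -> sum).  Annotated genes without data are imputed with the median
weight over measured genes; reactions without any gene association
receive the median weight over GPR-weighted reactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .gpr import evaluate_gpr, gpr_genes
from .model import MetabolicModel

#: Cap on z-scores for p-values that underflow the normal quantile.
Z_CAP = 8.0

#: Minimum number of finite values required to attempt a mixture fit.
MIN_BIMODAL_N = 4

EXPRESSION_COLUMNS = ["gene", "condition", "time_min", "value"]
DIFFERENTIAL_COLUMNS = ["gene", "condition", "time_min", "p_value", "direction"]


def pvalue_to_zscore(p, cap: float = Z_CAP):
    """Two-sided z-score of a p-value: ``z = Phi^-1(1 - p/2)``, capped.

    Direction-agnostic significance magnitude; the indicator I carries
    the sign.  Accepts scalars or arrays.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    z = norm.ppf(1.0 - p_arr / 2.0)
    z = np.minimum(z, cap)
    return float(z) if np.isscalar(p) or p_arr.ndim == 0 else z


@dataclass
class ThresholdFit:
    theta: float
    bimodal: bool
    means: tuple[float, float] | None = None


def fit_bimodal_threshold(
    values,
    seed: int = 0,
    n_init: int = 5,
    min_separation: float = 1e-9,
) -> ThresholdFit:
    """Gene activation threshold from a two-component Gaussian mixture.

    Fits 1- and 2-component univariate mixtures by EM (``n_init``
    restarts, fixed seed).  If the 2-component fit wins by BIC, the
    threshold is the point between the two means where the posterior
    responsibilities are equal; otherwise — or for degenerate input
    (fewer than 4 values, zero variance, coincident means) — the sample
    median with ``bimodal=False``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < MIN_BIMODAL_N or np.ptp(x) <= 0:
        theta = float(np.median(x)) if len(x) else math.nan
        return ThresholdFit(theta=theta, bimodal=False)

    X = x.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=seed).fit(X)
    gm2 = GaussianMixture(2, n_init=n_init, random_state=seed).fit(X)
    if gm2.bic(X) >= gm1.bic(X):
        return ThresholdFit(theta=float(np.median(x)), bimodal=False)

    order = np.argsort(gm2.means_.ravel())
    mu = gm2.means_.ravel()[order]
    var = gm2.covariances_.ravel()[order]
    pi = gm2.weights_.ravel()[order]
    if mu[1] - mu[0] <= min_separation:
        return ThresholdFit(theta=float(np.median(x)), bimodal=False)

    theta = _equal_responsibility_boundary(mu, var, pi)
    return ThresholdFit(theta=theta, bimodal=True, means=(float(mu[0]), float(mu[1])))


def _equal_responsibility_boundary(mu, var, pi) -> float:
    """Point between two Gaussian means with equal posterior responsibility.

    Solves pi0*N(x|mu0,var0) = pi1*N(x|mu1,var1), a quadratic in x;
    falls back to the midpoint if no root lies between the means.
    """
    a = 0.5 * (1.0 / var[0] - 1.0 / var[1])
    b = mu[1] / var[1] - mu[0] / var[0]
    c = (
        0.5 * (mu[0] ** 2 / var[0] - mu[1] ** 2 / var[1])
        + math.log(pi[0] / pi[1])
        + 0.5 * math.log(var[1] / var[0])
    )
    if abs(a) < 1e-12:  # equal variances -> linear equation
        if abs(b) < 1e-12:
            return float(0.5 * (mu[0] + mu[1]))
        roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            return float(0.5 * (mu[0] + mu[1]))
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if mu[0] < r < mu[1]]
    if not inside:
        return float(0.5 * (mu[0] + mu[1]))
    return float(inside[0])


def compute_gene_weight(I: int, z: float, xi: float, theta: float) -> float:
    """The gene weight ``w = I*z + (xi - theta)/theta``; requires theta > 0."""
    if theta <= 0:
        raise ValueError(f"threshold must be positive, got {theta}")
    return I * z + (xi - theta) / theta


def build_gene_weight_table(
    expression: pd.DataFrame,
    differential: pd.DataFrame | None,
    alpha: float = 0.05,
    z_cap: float = Z_CAP,
    seed: int = 0,
    shift_eps: float = 1e-3,
) -> pd.DataFrame:
    """Per-(gene, condition, time) weight table.

    Parameters
    ----------
    expression : DataFrame with columns gene, condition, time_min, value
    differential : DataFrame with columns gene, condition, time_min,
        p_value, direction ("up"/"down"/"none"); missing rows mean no
        differential evidence (I = 0, z = 0).
    alpha : significance level gating the indicator.
    shift_eps : genes whose pooled values include non-positive numbers
        are shifted so their minimum equals ``shift_eps`` before
        threshold fitting; xi is evaluated on the same shifted scale so
        theta > 0 always holds.

    Returns
    -------
    DataFrame with columns gene, condition, time_min, value, theta,
    bimodal, shift, p_value, direction, z, I, weight.
    """
    expr = expression.copy()
    missing = [c for c in EXPRESSION_COLUMNS if c not in expr.columns]
    if missing:
        raise ValueError(f"expression table lacks columns {missing}")
    if expr.duplicated(["gene", "condition", "time_min"]).any():
        raise ValueError("duplicate (gene, condition, time_min) keys in expression")

    # threshold per gene, pooled over all conditions and time points
    theta_rows = {}
    for gene, grp in expr.groupby("gene", sort=False):
        vals = grp["value"].to_numpy(float)
        shift = 0.0
        finite = vals[np.isfinite(vals)]
        if len(finite) and finite.min() <= 0:
            shift = shift_eps - finite.min()
        fit = fit_bimodal_threshold(vals + shift, seed=seed)
        theta_rows[gene] = (fit.theta, fit.bimodal, shift)
    theta_df = pd.DataFrame(
        [(g, *v) for g, v in theta_rows.items()],
        columns=["gene", "theta", "bimodal", "shift"],
    )

    out = expr.merge(theta_df, on="gene", how="left")
    if differential is not None and len(differential):
        de = differential[DIFFERENTIAL_COLUMNS].copy()
        out = out.merge(de, on=["gene", "condition", "time_min"], how="left")
    else:
        out["p_value"] = np.nan
        out["direction"] = "none"
    out["direction"] = out["direction"].fillna("none")

    has_p = out["p_value"].notna()
    z = np.zeros(len(out))
    z[has_p.to_numpy()] = pvalue_to_zscore(
        out.loc[has_p, "p_value"].to_numpy(), cap=z_cap
    )
    out["z"] = z

    sign = out["direction"].map({"up": 1, "down": -1}).fillna(0).astype(int)
    significant = has_p & (out["p_value"] <= alpha)
    out["I"] = np.where(significant, sign, 0)

    xi = out["value"].to_numpy(float) + out["shift"].to_numpy(float)
    theta = out["theta"].to_numpy(float)
    if np.any(theta <= 0):
        bad = out.loc[theta <= 0, "gene"].unique()
        raise ValueError(f"non-positive thresholds for genes {bad}")
    out["weight"] = out["I"].to_numpy() * out["z"].to_numpy() + (xi - theta) / theta
    return out


def map_weights_to_reactions(
    model: MetabolicModel, gene_weights: pd.DataFrame
) -> pd.DataFrame:
    """Map gene weights onto reactions through GPR rules.

    Per (condition, time): GPR trees are evaluated with AND -> min and
    OR -> sum; genes annotated in the model but missing from the table
    are imputed with the median weight over measured genes
    (provenance ``gene-median``); reactions without a GPR receive the
    median over GPR-weighted reactions (provenance ``reaction-median``).

    Returns a DataFrame with columns reaction, condition, time_min,
    weight, provenance.
    """
    rows = []
    for (cond, t), grp in gene_weights.groupby(["condition", "time_min"], sort=True):
        wmap = dict(zip(grp["gene"], grp["weight"]))
        gene_median = float(np.median(list(wmap.values()))) if wmap else 0.0

        gpr_weights = {}
        imputed = {}
        for rid in model.reactions:
            node = model.gpr.get(rid)
            if node is None:
                continue
            genes = gpr_genes(node)
            n_missing = sum(g not in wmap for g in genes)
            value = evaluate_gpr(node, lambda g: wmap.get(g, gene_median))
            gpr_weights[rid] = value
            imputed[rid] = n_missing > 0

        reaction_median = (
            float(np.median(list(gpr_weights.values()))) if gpr_weights else 0.0
        )
        for rid in model.reactions:
            if rid in gpr_weights:
                prov = "gene-median" if imputed[rid] else "gpr"
                w = gpr_weights[rid]
            else:
                prov = "reaction-median"
                w = reaction_median
            rows.append(
                {
                    "reaction": rid,
                    "condition": cond,
                    "time_min": t,
                    "weight": w,
                    "provenance": prov,
                }
            )
    return pd.DataFrame(rows)


def weights_for(
    reaction_weights: pd.DataFrame, condition: str, time_min
) -> pd.Series:
    """Weight vector (reaction id -> w) for one condition and time point."""
    sel = reaction_weights[
        (reaction_weights["condition"] == condition)
        & (reaction_weights["time_min"] == time_min)
    ]
    return pd.Series(sel["weight"].to_numpy(), index=sel["reaction"].to_numpy())
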