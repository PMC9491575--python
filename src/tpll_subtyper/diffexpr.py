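"""Subgroup-vs-control differential expression with empirical-Bayes
variance moderation.

Per gene, a one-way linear model over the four groups (control baseline)
gives a log2 fold change per tumor subgroup and a pooled residual variance
s² on d = n − #groups degrees of freedom.  The gene-wise variances are then
shrunk toward a common prior: s² is modeled as scaled-χ² around a prior
variance s0² with d0 prior degrees of freedom, the hyperparameters estimated
by moment matching on log s² (digamma/trigamma identities), and the
posterior variance

    s̃² = (d0·s0² + d·s²) / (d0 + d)

replaces s² in the t-statistic, which then has d0 + d degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import ExpressionMatrix
from .stats_core import bh_adjust

GROUPS = ("control", "SG1", "SG2", "SG3")


@dataclass
class GroupFit:
    """Per-gene OLS summaries of the one-way group model."""

    coefficients: pd.DataFrame  # gene × contrast log2 fold changes
    s2: pd.Series               # pooled residual variance per gene
    df_residual: int
    group_sizes: dict[str, int]

    def unscaled_variance(self, contrast: str) -> float:
        # Var(mean_g − mean_ctrl) = σ²·(1/n_g + 1/n_ctrl)
        return 1.0 / self.group_sizes[contrast] + 1.0 / self.group_sizes["control"]


@dataclass
class ModeratedStats:
    """Moderated t results for one contrast (tumor subgroup vs control)."""

    table: pd.DataFrame  # gene, log2fc, s2, s2_post, t, p, q, direction
    d0: float
    s02: float
    df_total: float


def fit_group_models(matrix: ExpressionMatrix, groups: pd.Series | dict,
                     baseline: str = "control") -> GroupFit:
    """One-way linear model per gene; contrasts are group-mean minus
    baseline-mean with a single pooled residual variance."""
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    groups = groups.reindex(matrix.sample_ids)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])[:5]
        raise ValueError(f"samples without group label: {missing}")
    levels = list(pd.unique(groups))
    if baseline not in levels:
        raise ValueError(f"baseline group {baseline!r} not present")
    sizes = groups.value_counts().to_dict()
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"groups with <2 samples: {small}")

    arr = matrix.values.to_numpy()
    n = arr.shape[1]
    k = len(levels)
    means = {}
    rss = np.zeros(arr.shape[0])
    for g in levels:
        cols = np.asarray(groups.to_numpy() == g)
        sub = arr[:, cols]
        mu = sub.mean(axis=1)
        means[g] = mu
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
    d = n - k
    s2 = pd.Series(rss / d, index=matrix.gene_ids, name="s2")
    coefs = pd.DataFrame(
        {g: means[g] - means[baseline] for g in levels if g != baseline},
        index=matrix.gene_ids,
    )
    return GroupFit(coefficients=coefs, s2=s2, df_residual=d, group_sizes=sizes)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, cf. the
    standard EB moment-matching recipe); returns inf for x <= 0."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(s2: pd.Series | np.ndarray, d: int) -> tuple[float, float, np.ndarray]:
    """Estimate (d0, s0²) from the gene-wise variances and return the
    posterior variances s̃².

    Moment matching on z = log s²: E z = log s0² + ψ(d/2) − log(d/2) −
    (ψ(d0/2) − log(d0/2)) and Var z = ψ′(d/2) + ψ′(d0/2).  If the observed
    variance of z does not exceed ψ′(d/2) the prior is degenerate
    (d0 = ∞, full shrinkage to the common value).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if positive.sum() < 10:
        raise ValueError("need >=10 genes with positive residual variance")
    z = np.log(s2[positive])
    # center z so that e has mean log(s0^2) under the model
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, d / 2.0)
    d0 = 2.0 * _trigamma_inverse(evar) if evar > 0 else np.inf
    if np.isinf(d0):
        if np.var(z) < 1e-15:  # all variances identical: no sampling spread
            s02 = float(np.exp(np.mean(z)))
        else:
            s02 = float(np.exp(np.mean(e)))
    else:
        s02 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        s2_post[~positive] = s02
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
    return d0, s02, s2_post


def moderated_t_test(fit: GroupFit, contrast: str,
                     d0: float, s02: float, s2_post: np.ndarray,
                     q_cutoff: float = 0.05) -> ModeratedStats:
    """Moderated t-test of one contrast with BH q-values over all genes."""
    beta = fit.coefficients[contrast].to_numpy()
    v = fit.unscaled_variance(contrast)
    df_total = d0 + fit.df_residual if np.isfinite(d0) else np.inf
    se = np.sqrt(s2_post * v)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    direction = np.where(q <= q_cutoff, np.where(beta > 0, "+", "-"), "=")
    table = pd.DataFrame(
        {
            "log2fc": beta,
            "s2": fit.s2.to_numpy(),
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "q": q,
            "direction": direction,
        },
        index=fit.coefficients.index,
    )
    return ModeratedStats(table=table, d0=d0, s02=s02, df_total=df_total)


def differential_expression(matrix: ExpressionMatrix, groups,
                            q_cutoff: float = 0.05) -> dict[str, ModeratedStats]:
    """Full workflow: group fit, EB moderation, one moderated t per subgroup
    contrast.  Genes with zero residual variance everywhere are excluded from
    hyperparameter estimation but still scored (their posterior variance is
    the prior)."""
    fit = fit_group_models(matrix, groups)
    d0, s02, s2_post = moderate_variances(fit.s2, fit.df_residual)
    return {
        c: moderated_t_test(fit, c, d0, s02, s2_post, q_cutoff=q_cutoff)
        for c in fit.coefficients.columns
    }


def de_sets(results: dict[str, ModeratedStats], q_cutoff: float = 0.05) -> dict:
    """Per-contrast up/down/any differential gene sets at the q cutoff."""
    out = {}
    for c, res in results.items():
        t = res.table
        sig = t.index[t["q"] <= q_cutoff]
        up = t.index[(t["q"] <= q_cutoff) & (t["log2fc"] > 0)]
        down = t.index[(t["q"] <= q_cutoff) & (t["log2fc"] < 0)]
        out[c] = {"any": set(sig), "up": set(up), "down": set(down)}
    return out


def de_overlaps(set_a: set, set_b: set, set_c: set,
                names=("SG1", "SG2", "SG3")) -> dict[str, int]:
    """The 7 disjoint Venn region counts of three gene sets, plus the union."""
    a, b, c = map(set, (set_a, set_b, set_c))
    na, nb, nc = names
    regions = {
        f"{na}_only": len(a - b - c),
        f"{nb}_only": len(b - a - c),
        f"{nc}_only": len(c - a - b),
        f"{na}_{nb}": len((a & b) - c),
        f"{na}_{nc}": len((a & c) - b),
        f"{nb}_{nc}": len((b & c) - a),
        f"{na}_{nb}_{nc}": len(a & b & c),
        "union": len(a | b | c),
    }
    return regions
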