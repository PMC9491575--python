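"""Ensemble lasso gene-regulatory-network inference from paired expression
and copy-number data.

Each gene's expression is modeled as a linear combination of its own gene
copy number and the expression of all other genes (in the differential-gene
universe).  Predictors entering the lasso path are scored with the
covariance test: at the k-th knot the statistic

    T_k = (⟨y, X·β(λ_{k+1})⟩ − ⟨y, X_A·β̃_A(λ_{k+1})⟩) / σ̂²

is asymptotically Exp(1) under the null that the entering predictor is
irrelevant, giving p = exp(−T_k).  Links are retained at a network-wide BH
q cutoff, coefficients refit by least squares, and the whole inference is
repeated over random training subsets; links supported by enough runs form
the consensus network, whose densely connected cores are the gene modules.

Prediction quality is the per-gene Pearson correlation between predicted
and observed expression on each run's held-out samples, compared against
degree-preserving random rewirings of the same networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import lars_path

from .stats_core import bh_adjust, wilcoxon_signed_rank

CN_PREDICTOR = "__own_cn__"


@dataclass
class CandidateLink:
    predictor: str
    entry_order: int
    T: float
    p: float
    beta: float = 0.0      # filled after refit
    q: float = float("nan")
    retained: bool = False


@dataclass
class GeneModel:
    target: str
    intercept: float = 0.0
    cn_coefficient: float = 0.0
    candidates: list[CandidateLink] = field(default_factory=list)

    @property
    def retained_predictors(self) -> list[CandidateLink]:
        return [c for c in self.candidates if c.retained and c.predictor != CN_PREDICTOR]


@dataclass
class NetworkRun:
    train_ids: list[str]
    test_ids: list[str]
    models: dict[str, GeneModel]
    seed: int


@dataclass
class NetworkEnsemble:
    runs: list[NetworkRun]
    gene_ids: list[str]
    link_q: float
    seed: int


# ---------------------------------------------------------------------------
# single-gene model


def _interp_coefs(alphas: np.ndarray, coefs: np.ndarray, a: float) -> np.ndarray:
    """Piecewise-linear coefficient vector of a lars path at penalty ``a``
    (alphas decreasing along the path)."""
    if a >= alphas[0]:
        return np.zeros(coefs.shape[0])
    if a <= alphas[-1]:
        return coefs[:, -1].copy()
    idx = int(np.searchsorted(-alphas, -a))  # alphas[idx-1] > a >= alphas[idx]
    lo, hi = alphas[idx], alphas[idx - 1]
    w = (a - lo) / (hi - lo) if hi > lo else 0.0
    return coefs[:, idx] * (1.0 - w) + coefs[:, idx - 1] * w


def covariance_test_path(X: np.ndarray, y: np.ndarray,
                         max_steps: int = 10) -> list[tuple[int, float]]:
    """Covariance-test statistics for the first ``max_steps`` lasso knots.

    Returns (predictor column index, T_k) per entering event, in entry order.
    ``X`` columns should be standardized and ``y`` centered; T_k is on the
    σ² = 1 scale — divide by an independent σ̂² before the Exp(1) tail.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alphas, active, coefs = lars_path(X, y, method="lasso",
                                          max_iter=max_steps)
    events: list[tuple[int, float]] = []
    seen: list[int] = []
    for k, var in enumerate(active):
        if k + 1 >= len(alphas):
            break
        a_next = alphas[k + 1]
        full_fit = float(y @ (X @ coefs[:, k + 1]))
        if seen:
            XA = X[:, seen]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a_A, _, c_A = lars_path(XA, y, method="lasso")
            beta_A = _interp_coefs(a_A, c_A, a_next)
            reduced_fit = float(y @ (XA @ beta_A))
        else:
            reduced_fit = 0.0
        events.append((int(var), full_fit - reduced_fit))
        seen.append(int(var))
    return events


def _cv_sigma2(X: np.ndarray, y: np.ndarray, max_steps: int,
               n_folds: int = 10, rng: np.random.Generator | None = None) -> float:
    """σ̂² for the covariance test: residual variance of the OLS refit on the
    active set at the λ minimizing k-fold cross-validated error over the
    knots of the full-data path."""
    n = X.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alphas, _, coefs = lars_path(X, y, method="lasso", max_iter=max_steps)
    if len(alphas) < 2:
        return float(np.var(y, ddof=1)) if n > 1 else 1.0
    folds = np.arange(n) % min(n_folds, n)
    if rng is not None:
        folds = rng.permutation(folds)
    cv_err = np.zeros(len(alphas))
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a_f, _, c_f = lars_path(X[tr], y[tr], method="lasso",
                                    max_iter=max_steps)
        betas = np.column_stack([_interp_coefs(a_f, c_f, a) for a in alphas])
        resid = y[te, None] - X[te] @ betas
        cv_err += (resid**2).sum(axis=0)
    best = int(np.argmin(cv_err))
    active = np.flatnonzero(np.abs(coefs[:, best]) > 0)
    if active.size == 0 or n - active.size - 1 <= 0:
        return float(np.var(y, ddof=1)) if n > 1 else 1.0
    XA = X[:, active]
    beta, *_ = np.linalg.lstsq(XA, y, rcond=None)
    resid = y - XA @ beta
    return float((resid @ resid) / (n - active.size - 1))


def _fit_from_arrays(target: str, y: np.ndarray, X: np.ndarray,
                     names: list[str], max_steps: int, cv_folds: int,
                     rng: np.random.Generator | None) -> GeneModel:
    model = GeneModel(target=target)
    if X.shape[1] == 0 or y.std() == 0:
        return model
    try:
        events = covariance_test_path(X, y, max_steps=max_steps)
    except Exception:  # path failure → intercept-only model
        return model
    if not events:
        return model
    sigma2 = _cv_sigma2(X, y, max_steps=max_steps, n_folds=cv_folds, rng=rng)
    sigma2 = max(sigma2, 1e-12)
    for order, (col, T_raw) in enumerate(events, start=1):
        T = T_raw / sigma2
        p = float(np.exp(-T)) if T > 0 else 1.0
        model.candidates.append(CandidateLink(
            predictor=names[col], entry_order=order, T=T, p=min(p, 1.0)))
    return model


def fit_gene_model(target: str, expr_train: pd.DataFrame,
                   cn_train: pd.Series | None,
                   max_steps: int = 10,
                   cv_folds: int = 10,
                   rng: np.random.Generator | None = None) -> GeneModel:
    """Lasso path + covariance test for one target gene on training samples.

    ``expr_train`` is gene × sample (training only).  Candidate predictors
    are the z-scored other genes plus (optionally) the target's own z-scored
    copy number.  Retention and refit happen at the network level once all
    link p-values are known.
    """
    y = expr_train.loc[target].to_numpy(dtype=float)
    y = y - y.mean()
    names: list[str] = []
    cols: list[np.ndarray] = []
    if cn_train is not None:
        v = cn_train.to_numpy(dtype=float)
        if np.nanstd(v) > 0:
            v = np.nan_to_num(v, nan=float(np.nanmean(v)))
            cols.append((v - v.mean()) / v.std())
            names.append(CN_PREDICTOR)
    for g in expr_train.index:
        if g == target:
            continue
        v = expr_train.loc[g].to_numpy(dtype=float)
        s = v.std()
        if s == 0:
            continue  # constant predictor dropped
        cols.append((v - v.mean()) / s)
        names.append(g)
    X = np.column_stack(cols) if cols else np.empty((y.size, 0))
    return _fit_from_arrays(target, y, X, names, max_steps, cv_folds, rng)


def _refit_models(models: dict[str, GeneModel], expr_train: pd.DataFrame,
                  cn_train: pd.DataFrame | None) -> None:
    """OLS refit of every model on its retained predictors (raw scale)."""
    for target, model in models.items():
        retained = [c for c in model.candidates if c.retained]
        y = expr_train.loc[target].to_numpy(dtype=float)
        if not retained:
            model.intercept = float(y.mean())
            continue
        cols = []
        for c in retained:
            if c.predictor == CN_PREDICTOR:
                v = cn_train.loc[target].to_numpy(dtype=float)
                v = np.nan_to_num(v, nan=float(np.nanmean(v)))
            else:
                v = expr_train.loc[c.predictor].to_numpy(dtype=float)
            cols.append(v)
        X = np.column_stack([np.ones_like(y)] + cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        model.intercept = float(beta[0])
        for c, b in zip(retained, beta[1:]):
            c.beta = float(b)
            if c.predictor == CN_PREDICTOR:
                model.cn_coefficient = float(b)


def infer_network(expr: pd.DataFrame, cn: pd.DataFrame | None,
                  train_ids: list[str], link_q: float = 0.01,
                  max_steps: int = 10, cv_folds: int = 10,
                  seed: int | None = None) -> dict[str, GeneModel]:
    """One network: a gene model per target, network-wide BH over all tested
    links, retention at ``link_q``, least-squares refit."""
    if len(train_ids) < 10:
        raise ValueError("need >=10 training samples")
    rng = np.random.default_rng(seed)
    expr_train = expr[train_ids]
    cn_train = cn[train_ids] if cn is not None else None
    # standardize everything once; per target, drop its own column
    E = expr_train.to_numpy(dtype=float).T          # n × p
    sd = E.std(axis=0)
    keep = sd > 0
    Z = np.zeros_like(E)
    Z[:, keep] = (E[:, keep] - E[:, keep].mean(axis=0)) / sd[keep]
    gene_list = list(expr_train.index)
    col_of = {g: i for i, g in enumerate(gene_list)}
    if cn_train is not None:
        C = cn_train.to_numpy(dtype=float).T
        C[:, np.all(np.isnan(C), axis=0)] = 0.0  # genes without probe coverage
        C = np.where(np.isnan(C), np.nanmean(C, axis=0, keepdims=True), C)
        csd = C.std(axis=0)
        Cz = np.zeros_like(C)
        Cz[:, csd > 0] = (C[:, csd > 0] - C[:, csd > 0].mean(axis=0)) / csd[csd > 0]
        cn_genes = {g: i for i, g in enumerate(cn_train.index)}
    models = {}
    pred_genes = [g for g in gene_list if keep[col_of[g]]]
    for target in gene_list:
        j = col_of[target]
        y = E[:, j] - E[:, j].mean()
        other = [g for g in pred_genes if g != target]
        cols = [Z[:, col_of[g]] for g in other]
        names = list(other)
        if cn_train is not None and target in cn_genes and csd[cn_genes[target]] > 0:
            cols.insert(0, Cz[:, cn_genes[target]])
            names.insert(0, CN_PREDICTOR)
        X = np.column_stack(cols) if cols else np.empty((y.size, 0))
        models[target] = _fit_from_arrays(target, y, X, names,
                                          max_steps, cv_folds, rng)
    all_links = [(t, c) for t, m in models.items() for c in m.candidates]
    if all_links:
        qs = bh_adjust([c.p for _, c in all_links])
        for (t, c), q in zip(all_links, qs):
            c.q = float(q)
            c.retained = q <= link_q
    _refit_models(models, expr_train, cn_train)
    return models


def infer_ensemble(expr: pd.DataFrame, cn: pd.DataFrame | None,
                   n_runs: int = 100, train_fraction: float = 2.0 / 3.0,
                   link_q: float = 0.01, max_steps: int = 10,
                   cv_folds: int = 10, seed: int | None = None) -> NetworkEnsemble:
    """Repeat network inference over random training subsets.

    The training size is round(train_fraction · n); the complement is that
    run's test set (e.g. 35 train / 18 test out of 53 paired samples)."""
    samples = list(expr.columns)
    if len(samples) < 20:
        raise ValueError("need >=20 paired samples")
    if not (0.5 < train_fraction < 0.9):
        warnings.warn("train_fraction outside (0.5, 0.9)")
    n_train = int(round(train_fraction * len(samples)))
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_runs):
        run_seed = int(rng.integers(2**31))
        run_rng = np.random.default_rng(run_seed)
        train = sorted(run_rng.choice(samples, size=n_train, replace=False))
        test = [s for s in samples if s not in set(train)]
        models = infer_network(expr, cn, train, link_q=link_q,
                               max_steps=max_steps, cv_folds=cv_folds,
                               seed=run_seed)
        runs.append(NetworkRun(train_ids=list(train), test_ids=test,
                               models=models, seed=run_seed))
    return NetworkEnsemble(runs=runs, gene_ids=list(expr.index),
                           link_q=link_q, seed=seed if seed is not None else -1)


# ---------------------------------------------------------------------------
# prediction quality vs degree-preserving nulls


def _predict_run(models: dict[str, GeneModel], expr: pd.DataFrame,
                 cn: pd.DataFrame | None, test_ids: list[str]) -> pd.DataFrame:
    pred = {}
    for target, m in models.items():
        yhat = np.full(len(test_ids), m.intercept)
        for c in m.candidates:
            if not c.retained:
                continue
            if c.predictor == CN_PREDICTOR:
                v = cn.loc[target, test_ids].to_numpy(dtype=float)
                v = np.nan_to_num(v, nan=0.0)
            else:
                v = expr.loc[c.predictor, test_ids].to_numpy(dtype=float)
            yhat = yhat + c.beta * v
        pred[target] = yhat
    return pd.DataFrame(pred, index=test_ids).T


def prediction_quality(ensemble: NetworkEnsemble, expr: pd.DataFrame,
                       cn: pd.DataFrame | None,
                       runs: list[NetworkRun] | None = None) -> pd.Series:
    """Per-gene mean test-set Pearson correlation across the ensemble's runs.

    Genes whose predictions are constant in a run (e.g. no retained links)
    contribute NA for that run; runs with < 3 test samples are skipped."""
    runs = ensemble.runs if runs is None else runs
    acc = pd.DataFrame(index=ensemble.gene_ids,
                       columns=range(len(runs)), dtype=float)
    for ri, run in enumerate(runs):
        if len(run.test_ids) < 3:
            warnings.warn(f"run {ri}: test set < 3 samples, skipped")
            continue
        pred = _predict_run(run.models, expr, cn, run.test_ids)
        obs = expr[run.test_ids]
        p = pred.to_numpy(dtype=float)
        o = obs.loc[pred.index].to_numpy(dtype=float)
        ps = p.std(axis=1)
        os_ = o.std(axis=1)
        ok = (ps > 0) & (os_ > 0)
        r = np.full(p.shape[0], np.nan)
        pc = p - p.mean(axis=1, keepdims=True)
        oc = o - o.mean(axis=1, keepdims=True)
        num = (pc * oc).sum(axis=1)
        den = np.sqrt((pc**2).sum(axis=1) * (oc**2).sum(axis=1))
        r[ok] = num[ok] / den[ok]
        acc.loc[pred.index, ri] = r
    return acc.mean(axis=1, skipna=True)


def _rewire_run(run: NetworkRun, rng: np.random.Generator) -> dict[str, GeneModel]:
    """Degree-preserving rewiring of the run's retained gene→gene links.

    Repeated pair swaps keep every predictor's out-degree and every target's
    in-degree; self-links and duplicate links are rejected.  CN links stay
    attached to their target."""
    edges = []
    for target, m in run.models.items():
        for c in m.retained_predictors:
            edges.append([c.predictor, target])
    n = len(edges)
    if n >= 2:
        existing = {(p, t) for p, t in edges}
        for _ in range(10 * n):
            a, b = rng.integers(0, n, size=2)
            if a == b:
                continue
            p1, t1 = edges[a]
            p2, t2 = edges[b]
            if p1 == t2 or p2 == t1:
                continue
            if (p1, t2) in existing or (p2, t1) in existing:
                continue
            existing -= {(p1, t1), (p2, t2)}
            edges[a] = [p1, t2]
            edges[b] = [p2, t1]
            existing |= {(p1, t2), (p2, t1)}
    by_target: dict[str, list[str]] = {}
    for p, t in edges:
        by_target.setdefault(t, []).append(p)
    null_models: dict[str, GeneModel] = {}
    for target, m in run.models.items():
        nm = GeneModel(target=target)
        preds = by_target.get(target, [])
        order = 1
        for c in m.candidates:  # keep CN links in place
            if c.retained and c.predictor == CN_PREDICTOR:
                nm.candidates.append(CandidateLink(
                    predictor=CN_PREDICTOR, entry_order=order, T=c.T,
                    p=c.p, retained=True))
                order += 1
        for p in preds:
            nm.candidates.append(CandidateLink(
                predictor=p, entry_order=order, T=0.0, p=1.0, retained=True))
            order += 1
        null_models[target] = nm
    return null_models


def compare_to_null(ensemble: NetworkEnsemble, expr: pd.DataFrame,
                    cn: pd.DataFrame | None, n_null: int = 10,
                    seed: int | None = None) -> dict:
    """Real vs degree-preserving-null prediction quality.

    Null networks are rewired per run, refit by least squares on that run's
    training set, and evaluated on the same test sets.  Returns per-gene
    real and null (averaged) correlations, their paired differences, the
    median difference, and the signed-rank test on the pairs."""
    rng = np.random.default_rng(seed)
    real = prediction_quality(ensemble, expr, cn)
    null_reps = []
    for _ in range(n_null):
        null_runs = []
        for run in ensemble.runs:
            nm = _rewire_run(run, rng)
            _refit_models(nm, expr[run.train_ids],
                          cn[run.train_ids] if cn is not None else None)
            null_runs.append(NetworkRun(train_ids=run.train_ids,
                                        test_ids=run.test_ids,
                                        models=nm, seed=run.seed))
        null_reps.append(prediction_quality(ensemble, expr, cn, runs=null_runs))
    null = pd.concat(null_reps, axis=1).mean(axis=1, skipna=True)
    paired = pd.DataFrame({"real": real, "null": null}).dropna()
    diff = paired["real"] - paired["null"]
    test = wilcoxon_signed_rank(diff.to_numpy()) if len(diff) else None
    return {
        "real": real,
        "null": null,
        "differences": diff,
        "median_difference": float(diff.median()) if len(diff) else float("nan"),
        "median_real": float(real.dropna().median()) if real.notna().any() else float("nan"),
        "signed_rank": test,
    }


# ---------------------------------------------------------------------------
# consensus network and modules


def consensus_and_modules(ensemble: NetworkEnsemble, support_min: int = 75,
                          min_links: int = 2, min_module: int = 3) -> dict:
    """Consensus links (support ≥ ``support_min`` runs) and their modules.

    A link between two genes is present in a run iff it was retained there
    in either direction (already at the ensemble's link-q cutoff); support
    is the number of runs in which it is present.  Modules are connected
    components of the consensus graph iteratively pruned of genes with fewer
    than ``min_links`` internal links, kept at ≥ ``min_module`` genes.  Link
    sign is the majority coefficient sign across supporting run-directions."""
    support: dict[frozenset, int] = {}
    signs: dict[frozenset, list[float]] = {}
    direction: dict[frozenset, tuple[str, str]] = {}
    for run in ensemble.runs:
        seen: set[frozenset] = set()
        for target, m in run.models.items():
            for c in m.retained_predictors:
                key = frozenset((c.predictor, target))
                if len(key) < 2:
                    continue
                signs.setdefault(key, []).append(np.sign(c.beta))
                direction.setdefault(key, (c.predictor, target))
                if key not in seen:
                    seen.add(key)
                    support[key] = support.get(key, 0) + 1
    links = []
    for key, s in support.items():
        if s >= support_min:
            sgn = 1 if sum(signs[key]) >= 0 else -1
            pred, tgt = direction[key]
            links.append({"predictor": pred, "target": tgt,
                          "support": s, "sign": sgn})
    g = nx.Graph()
    for l in links:
        g.add_edge(l["predictor"], l["target"],
                   support=l["support"], sign=l["sign"])
    # iterative pruning to the min_links core
    pruned = g.copy()
    while True:
        low = [n for n, d in pruned.degree() if d < min_links]
        if not low:
            break
        pruned.remove_nodes_from(low)
    modules = [sorted(comp) for comp in nx.connected_components(pruned)
               if len(comp) >= min_module]
    modules.sort(key=lambda m: (-len(m), m))
    return {
        "links": pd.DataFrame(links, columns=["predictor", "target",
                                              "support", "sign"]),
        "graph": g,
        "modules": modules,
    }


def annotate_module_expression(modules: list[list[str]],
                               de_results: dict[str, "object"],
                               q_cutoff: float = 0.05) -> pd.DataFrame:
    """Per module gene, the expression direction (−/=/+) in each subgroup
    relative to controls at the DE q cutoff."""
    rows = []
    for mi, module in enumerate(modules, start=1):
        for gene in module:
            row = {"module": mi, "gene": gene}
            for sg, res in de_results.items():
                table = res.table if hasattr(res, "table") else res
                if gene in table.index:
                    q = table.loc[gene, "q"]
                    fc = table.loc[gene, "log2fc"]
                    row[sg] = "+" if (q <= q_cutoff and fc > 0) else (
                        "-" if (q <= q_cutoff and fc < 0) else "=")
                else:
                    row[sg] = "="
                    row["flagged"] = True
            rows.append(row)
    return pd.DataFrame(rows)
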