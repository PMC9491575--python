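"""Cross-cohort subgroup transfer: parametric empirical-Bayes batch
adjustment followed by nearest-positive-correlation label assignment.

The batch adjustment is the standard parametric location/scale model: genes
are standardized by the pooled fit, per-batch additive (γ) and
multiplicative (δ) effects are estimated and shrunk toward common priors —
normal on γ, inverse-gamma on δ, hyperparameters by moments — via the EB
fixed-point iteration, and the data are back-transformed.  Each incoming
sample is then assigned the subgroup label of the reference sample with the
strongest positive Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix
from .stats_core import TestResult, fisher_exact_rxc

MIN_GENE_OVERLAP = 500


@dataclass
class TransferResult:
    sample_id: str
    label: object
    best_match: str | None
    correlation: float
    low_confidence: bool = False


def _aprior(gamma_hat: np.ndarray) -> float:
    m, s2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
    return float((2 * s2 + m**2) / s2)


def _bprior(gamma_hat: np.ndarray) -> float:
    m, s2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
    return float((m * s2 + m**3) / s2)


def _it_sol(s_data: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            conv: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """EB fixed-point iteration for one batch's γ*, δ* (parametric priors)."""
    n = s_data.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max(),
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_adjust(reference: ExpressionMatrix,
                  incoming: ExpressionMatrix | None
                  ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Joint batch adjustment of the two cohorts (genes intersected first).

    Returns the adjusted reference and incoming matrices on the common gene
    set.  With ``incoming=None`` there is a single batch and the adjustment
    is the identity; a batch with one sample is an error.
    """
    if incoming is None:
        return reference.values.copy(), None
    common = [g for g in reference.gene_ids if g in set(incoming.gene_ids)]
    if not common:
        raise ValueError("reference and incoming share no genes")
    ref = reference.values.loc[common]
    inc = incoming.values.loc[common]
    batches = [ref, inc]
    for b in batches:
        if b.shape[1] < 2:
            raise ValueError("each batch needs >=2 samples")
    joint = pd.concat(batches, axis=1)
    n_batches = [b.shape[1] for b in batches]
    n_total = sum(n_batches)
    data = joint.to_numpy(dtype=float)

    # pooled gene model (weighted grand mean over batches)
    batch_idx = np.repeat(np.arange(len(batches)), n_batches)
    batch_means = np.column_stack([data[:, batch_idx == i].mean(axis=1)
                                   for i in range(len(batches))])
    grand_mean = batch_means @ (np.array(n_batches) / n_total)
    var_pooled = ((data - batch_means[:, batch_idx]) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)
    s_data = (data - grand_mean[:, None]) / sd[:, None]

    adjusted = s_data.copy()
    for i in range(len(batches)):
        cols = batch_idx == i
        sb = s_data[:, cols]
        g_hat = sb.mean(axis=1)
        d_hat = sb.var(axis=1, ddof=1)
        d_hat = np.maximum(d_hat, 1e-12)
        g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
        a, b = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_sol(sb, g_hat, d_hat, g_bar, t2, a, b)
        adjusted[:, cols] = (sb - g_star[:, None]) / np.sqrt(d_star)[:, None]
    adjusted = adjusted * sd[:, None] + grand_mean[:, None]
    out = pd.DataFrame(adjusted, index=joint.index, columns=joint.columns)
    return out.iloc[:, : n_batches[0]], out.iloc[:, n_batches[0]:]


def transfer_labels(reference: pd.DataFrame, reference_labels: dict,
                    incoming: pd.DataFrame,
                    correlation_floor: float = 0.2) -> list[TransferResult]:
    """Assign each incoming sample the label of its best-correlated
    reference sample.

    Correlations are Pearson over the shared gene rows (≥ 500 enforced);
    ties break by reference column order.  A non-positive best correlation
    yields an unassignable result; a best correlation below the floor is
    flagged low-confidence.
    """
    common = reference.index.intersection(incoming.index)
    if len(common) < MIN_GENE_OVERLAP:
        raise ValueError(
            f"gene overlap {len(common)} below required {MIN_GENE_OVERLAP}")
    ref = reference.loc[common].to_numpy(dtype=float)
    inc = incoming.loc[common].to_numpy(dtype=float)
    refc = (ref - ref.mean(axis=0)) / ref.std(axis=0)
    incc = (inc - inc.mean(axis=0)) / inc.std(axis=0)
    corr = (incc.T @ refc) / len(common)  # incoming × reference
    results = []
    ref_ids = list(reference.columns)
    for si, sid in enumerate(incoming.columns):
        r = corr[si]
        best = int(np.argmax(r))  # argmax takes the first maximum: id-order tie-break
        best_r = float(r[best])
        if best_r <= 0:
            results.append(TransferResult(sample_id=str(sid), label=None,
                                          best_match=None, correlation=best_r,
                                          low_confidence=True))
            continue
        results.append(TransferResult(
            sample_id=str(sid),
            label=reference_labels.get(ref_ids[best]),
            best_match=str(ref_ids[best]),
            correlation=best_r,
            low_confidence=best_r < correlation_floor,
        ))
    return results


def compare_distributions(counts_a, counts_b) -> TestResult:
    """Exact Fisher test of two per-label count vectors (2 × k table)."""
    a = np.asarray(counts_a, dtype=int)
    b = np.asarray(counts_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("count vectors must have the same label set")
    return fisher_exact_rxc(np.vstack([a, b]))
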