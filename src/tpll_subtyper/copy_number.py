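"""Circular binary segmentation of copy-number log-ratios, gene-level
assignment, and subgroup median profiles.

Probe log2-ratios (tumor vs normal DNA) are segmented chromosome by
chromosome: the two-sample t statistic is maximized over all circular arcs
of the current segment, the split is accepted when its permutation p-value
(shuffling the probe order within the segment) is at most alpha, and the
procedure recurses into the emitted pieces.  Genes then receive the mean
log-ratio of the segment containing their midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

PROBE_COLUMNS = ["sample_id", "chrom", "pos", "log2ratio"]


@dataclass
class CopyNumberSegment:
    chrom: str
    start_index: int   # 0-based probe index, inclusive
    end_index: int     # exclusive
    start_bp: int
    end_bp: int
    n_probes: int
    mean: float


def _pair_indices(m: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All arc boundaries 0 <= i < j <= m with both arc and complement of
    length >= min_width."""
    i, j = np.meshgrid(np.arange(m + 1), np.arange(m + 1), indexing="ij")
    k = j - i
    mask = (k >= min_width) & ((m - k) >= min_width)
    return i[mask], j[mask]


def _max_arc_stat(x: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> tuple[float, int, int]:
    """Maximal |t| over the candidate arcs of one segment."""
    m = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    k = (jj - ii).astype(float)
    rest = m - k
    sum_in = cs[jj] - cs[ii]
    ssq_in = cs2[jj] - cs2[ii]
    sum_out = cs[m] - sum_in
    ssq_out = cs2[m] - ssq_in
    varp = (ssq_in - sum_in**2 / k + ssq_out - sum_out**2 / rest) / max(m - 2, 1)
    denom = np.sqrt(np.maximum(varp, 1e-300) * (1.0 / k + 1.0 / rest))
    t = np.abs(sum_in / k - sum_out / rest) / denom
    best = int(np.argmax(t))
    return float(t[best]), int(ii[best]), int(jj[best])


def _batch_max_stats(xs: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """Max |t| per row of a (B, m) batch of permuted segments."""
    B, m = xs.shape
    cs = np.concatenate([np.zeros((B, 1)), np.cumsum(xs, axis=1)], axis=1)
    cs2 = np.concatenate([np.zeros((B, 1)), np.cumsum(xs * xs, axis=1)], axis=1)
    k = (jj - ii).astype(float)
    rest = m - k
    sum_in = cs[:, jj] - cs[:, ii]
    ssq_in = cs2[:, jj] - cs2[:, ii]
    sum_out = cs[:, [m]] - sum_in
    ssq_out = cs2[:, [m]] - ssq_in
    varp = (ssq_in - sum_in**2 / k + ssq_out - sum_out**2 / rest) / max(m - 2, 1)
    denom = np.sqrt(np.maximum(varp, 1e-300) * (1.0 / k + 1.0 / rest))
    t = np.abs(sum_in / k - sum_out / rest) / denom
    return t.max(axis=1)


def _split_p_value(x: np.ndarray, observed: float, ii, jj,
                   alpha: float, n_perm: int, rng: np.random.Generator,
                   batch: int = 200) -> float:
    """Permutation p of the maximal arc statistic with early stopping once
    non-significance is guaranteed."""
    exceed = 0
    done = 0
    needed = int(np.floor(alpha * (n_perm + 1)))  # > needed exceedances => p > alpha
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.asarray([rng.permutation(x) for _ in range(b)])
        stats = _batch_max_stats(perms, ii, jj)
        exceed += int((stats >= observed).sum())
        done += b
        if exceed > needed:
            break
    return (exceed + 1) / (done + 1)


def segment_cbs(probes: pd.DataFrame, alpha: float = 0.01,
                n_perm: int = 1000, min_width: int = 2,
                seed: int | None = None) -> pd.DataFrame:
    """Segment one sample's probe series into regions of constant copy number.

    ``probes`` needs columns chrom, pos, log2ratio, sorted by position within
    each chromosome (strictly increasing).  Returns a BED-like frame with
    chrom, start_bp, end_bp, n_probes, mean (probes tile segments exactly).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value")
    rng = np.random.default_rng(seed)
    segments: list[CopyNumberSegment] = []
    for chrom, grp in probes.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"probe positions not strictly increasing on {chrom}")
        x = grp["log2ratio"].to_numpy(dtype=float)
        segments.extend(_segment_chrom(str(chrom), pos, x, alpha, n_perm,
                                       min_width, rng))
    return pd.DataFrame([s.__dict__ for s in segments])


def _segment_chrom(chrom: str, pos: np.ndarray, x: np.ndarray,
                   alpha: float, n_perm: int, min_width: int,
                   rng: np.random.Generator) -> list[CopyNumberSegment]:
    out: list[CopyNumberSegment] = []

    def emit(lo: int, hi: int) -> None:
        out.append(CopyNumberSegment(
            chrom=chrom, start_index=lo, end_index=hi,
            start_bp=int(pos[lo]), end_bp=int(pos[hi - 1]),
            n_probes=hi - lo, mean=float(x[lo:hi].mean()),
        ))

    def recurse(lo: int, hi: int) -> None:
        m = hi - lo
        if m < 2 * min_width:
            emit(lo, hi)
            return
        seg = x[lo:hi]
        if np.ptp(seg) == 0.0:
            emit(lo, hi)
            return
        ii, jj = _pair_indices(m, min_width)
        observed, bi, bj = _max_arc_stat(seg, ii, jj)
        p = _split_p_value(seg, observed, ii, jj, alpha, n_perm, rng)
        if p > alpha:
            emit(lo, hi)
            return
        cuts = sorted({lo, lo + bi, lo + bj, hi})
        for a, b in zip(cuts[:-1], cuts[1:]):
            recurse(a, b)

    recurse(0, x.size)
    out.sort(key=lambda s: s.start_index)
    return out


def segment_cohort(probe_table: pd.DataFrame, alpha: float = 0.01,
                   n_perm: int = 1000, min_width: int = 2,
                   seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Run CBS per sample of a long-format probe table (PROBE_COLUMNS)."""
    rng = np.random.default_rng(seed)
    return {
        str(sid): segment_cbs(grp.sort_values(["chrom", "pos"]), alpha=alpha,
                              n_perm=n_perm, min_width=min_width,
                              seed=int(rng.integers(2**31)))
        for sid, grp in probe_table.groupby("sample_id", sort=False)
    }


def map_genes_to_segments(segments_by_sample: dict[str, pd.DataFrame],
                          gene_coords: pd.DataFrame) -> pd.DataFrame:
    """Gene × sample log-ratio matrix: each gene takes the mean of the
    segment containing its midpoint (boundary bp → lower-coordinate segment);
    genes on chromosomes without probes get NA.

    ``gene_coords`` needs columns gene_id, chrom, start, end (1-based
    inclusive).
    """
    bad = gene_coords["start"] > gene_coords["end"]
    if bad.any():
        raise ValueError(
            f"malformed gene coordinates (start > end): "
            f"{list(gene_coords.loc[bad, 'gene_id'][:5])}"
        )
    mids = ((gene_coords["start"] + gene_coords["end"]) / 2.0).to_numpy()
    result = {}
    for sid, segs in segments_by_sample.items():
        values = np.full(len(gene_coords), np.nan)
        for chrom, seg_grp in segs.groupby("chrom", sort=False):
            seg_grp = seg_grp.sort_values("start_bp")
            starts = seg_grp["start_bp"].to_numpy(dtype=float)
            ends = seg_grp["end_bp"].to_numpy(dtype=float)
            means = seg_grp["mean"].to_numpy()
            sel = (gene_coords["chrom"] == chrom).to_numpy()
            if not sel.any():
                continue
            m = mids[sel]
            # first segment whose end >= midpoint; ties on the boundary go left
            idx = np.searchsorted(ends, m, side="left")
            ok = (idx < len(ends)) & (m >= starts[np.minimum(idx, len(ends) - 1)])
            vals = np.full(m.size, np.nan)
            vals[ok] = means[idx[ok]]
            values[sel] = vals
        result[sid] = values
    return pd.DataFrame(result, index=gene_coords["gene_id"].to_numpy())


def subgroup_median_profile(gene_cn: pd.DataFrame,
                            labels: dict[str, object]) -> pd.DataFrame:
    """Per-gene median log-ratio within each subgroup (NA-dropping)."""
    groups: dict[object, list[str]] = {}
    for s in gene_cn.columns:
        if s in labels:
            groups.setdefault(labels[s], []).append(s)
    if not groups:
        raise ValueError("no samples with subgroup labels")
    return pd.DataFrame({g: gene_cn[cols].median(axis=1, skipna=True)
                         for g, cols in sorted(groups.items(), key=lambda kv: str(kv[0]))})


def recurrent_alterations(gene_cn: pd.DataFrame, labels: dict[str, object],
                          call_threshold: float = 0.2) -> dict[str, pd.DataFrame]:
    """Per-gene per-subgroup frequencies of deletion (log-ratio <= -thr) and
    duplication (>= +thr) calls."""
    if call_threshold <= 0:
        raise ValueError("call_threshold must be positive")
    groups: dict[object, list[str]] = {}
    for s in gene_cn.columns:
        if s in labels:
            groups.setdefault(labels[s], []).append(s)
    out = {}
    for name, op in (("deletion", lambda v: v <= -call_threshold),
                     ("duplication", lambda v: v >= call_threshold)):
        freq = {}
        for g, cols in sorted(groups.items(), key=lambda kv: str(kv[0])):
            vals = gene_cn[cols]
            freq[g] = op(vals).sum(axis=1) / vals.notna().sum(axis=1).clip(lower=1)
        out[name] = pd.DataFrame(freq)
    return out
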