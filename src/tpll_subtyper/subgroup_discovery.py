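"""Hierarchical subgroup discovery with multiscale-bootstrap support and
patient-removal stability.

Samples are clustered on the correlation distance 1 − r (Pearson r across
genes) under Ward's ward.D2 linkage.  Cluster support is quantified two ways:

* multiscale gene bootstrap: genes are resampled with replacement at several
  relative sizes τ, the per-node bootstrap frequency BP_τ is recorded, and the
  probit-scale curve z_τ = v·√τ + c/√τ is fitted by weighted least squares,
  giving the approximately unbiased support AU = 1 − Φ(v − c) and the
  size-1 bootstrap probability BP = 1 − Φ(v + c);
* patient removal: a random subset of tumor samples is dropped, the clustering
  repeated, clusters re-paired to the reference by majority overlap, and the
  fraction of retained samples that land in their reference cluster recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .core_io import ExpressionMatrix


@dataclass
class DistanceMatrix:
    """Symmetric sample × sample correlation-distance matrix (zero diagonal)."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        d = self.values
        if d.shape[0] != d.shape[1] or d.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.isfinite(d).all():
            raise ValueError("non-finite distance")


@dataclass
class ClusterTree:
    """Agglomerative merge hierarchy over samples.

    ``linkage`` is the scipy (n−1) × 4 merge table; ``au``/``bp`` hold
    per-internal-node support in merge order once :func:`au_bootstrap` has
    been run.
    """

    linkage: np.ndarray
    sample_ids: list[str]
    au: np.ndarray | None = None
    bp: np.ndarray | None = None
    #: leaf-id frozensets per internal node, in merge order
    _node_sets: list[frozenset] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self._node_sets:
            self._node_sets = _merge_sets(self.linkage, len(self.sample_ids))

    @property
    def node_sets(self) -> list[frozenset]:
        return self._node_sets

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class SubgroupAssignment:
    """Sample → cluster label map with labels 1..k ordered left-to-right in
    the dendrogram."""

    labels: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        got = set(self.labels.values())
        if got != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k}, got {sorted(got)}")

    def members(self, label: int) -> set[str]:
        return {s for s, l in self.labels.items() if l == label}


def _merge_sets(Z: np.ndarray, n: int) -> list[frozenset]:
    sets: list[frozenset] = []
    lookup: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    for idx, (a, b, _, _) in enumerate(Z):
        merged = lookup[int(a)] | lookup[int(b)]
        lookup[n + idx] = merged
        sets.append(merged)
    return sets


def correlation_distance(matrix: ExpressionMatrix | np.ndarray,
                         sample_ids: list[str] | None = None) -> DistanceMatrix:
    """1 − Pearson correlation between sample expression profiles."""
    if isinstance(matrix, ExpressionMatrix):
        arr = matrix.values.to_numpy()
        sample_ids = matrix.sample_ids
    else:
        arr = np.asarray(matrix, dtype=float)
        if sample_ids is None:
            sample_ids = [f"S{i}" for i in range(arr.shape[1])]
    if arr.shape[0] < 2:
        raise ValueError("need >=2 genes to compute correlation distance")
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        bad = sample_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance sample: {bad!r}")
    r = np.corrcoef(arr, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(values=d, sample_ids=list(sample_ids))


def ward_cluster(d: DistanceMatrix) -> ClusterTree:
    """Agglomerate under the ward.D2 criterion (scipy 'ward' on the raw
    dissimilarities, i.e. the Lance–Williams recurrence on squared input)."""
    condensed = squareform(d.values, checks=False)
    Z = linkage(condensed, method="ward")
    return ClusterTree(linkage=Z, sample_ids=list(d.sample_ids))


def cut_tree(tree: ClusterTree, k: int) -> SubgroupAssignment:
    """Cut into k clusters by removing the k−1 highest merges; labels are
    numbered by dendrogram left-to-right order of first appearance."""
    n = len(tree.sample_ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = fcluster(tree.linkage, t=k, criterion="maxclust")
    order = leaves_list(tree.linkage)
    relabel: dict[int, int] = {}
    for leaf in order:
        c = raw[leaf]
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    labels = {tree.sample_ids[i]: relabel[raw[i]] for i in range(n)}
    return SubgroupAssignment(labels=labels, k=len(relabel))


def cluster_samples(matrix: ExpressionMatrix, genes=None) -> ClusterTree:
    """Convenience: correlation distance + Ward tree, optionally on a gene
    subset (e.g. re-clustering on differential genes only)."""
    m = matrix.subset_genes(genes) if genes is not None else matrix
    return ward_cluster(correlation_distance(m))


# ---------------------------------------------------------------------------
# multiscale bootstrap (AU support)

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))


def au_bootstrap(matrix: ExpressionMatrix,
                 n_total_runs: int = 10_000,
                 scales=DEFAULT_SCALES,
                 seed: int | None = None,
                 tree: ClusterTree | None = None) -> ClusterTree:
    """Multiscale gene bootstrap giving AU and BP support per internal node.

    ``n_total_runs`` bootstrap clusterings are split evenly across the
    relative resample sizes ``scales`` (which must bracket τ = 1).  Observed
    frequencies of exactly 0 or 1 are clamped to (ε, 1−ε), ε = 1/(2·reps per
    scale), before the probit transform.  Nodes never re-observed at any
    scale get AU = BP = 0.
    """
    scales = np.asarray(scales, dtype=float)
    if scales.size < 2 or scales.min() >= 1.0 or scales.max() <= 1.0:
        raise ValueError("scales must contain values below and above 1")
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = cluster_samples(matrix)
    arr = matrix.values.to_numpy()
    n_genes, n_samples = arr.shape
    reps = max(1, n_total_runs // scales.size)
    node_sets = tree.node_sets
    node_index = {s: i for i, s in enumerate(node_sets)}
    counts = np.zeros((scales.size, len(node_sets)), dtype=np.int64)
    for si, tau in enumerate(scales):
        m = int(np.ceil(tau * n_genes))
        for _ in range(reps):
            idx = rng.integers(0, n_genes, size=m)
            sub = arr[idx]
            sd = sub.std(axis=0)
            if np.any(sd == 0):  # degenerate resample; skip genes w/o variance
                sub = sub + rng.normal(0.0, 1e-9, size=sub.shape)
            r = np.corrcoef(sub, rowvar=False)
            d = 1.0 - r
            np.fill_diagonal(d, 0.0)
            Z = linkage(squareform(np.clip((d + d.T) / 2, 0, 2), checks=False),
                        method="ward")
            for s in _merge_sets(Z, n_samples):
                j = node_index.get(s)
                if j is not None:
                    counts[si, j] += 1

    eps = 1.0 / (2.0 * reps)
    bp_tau = np.clip(counts / reps, eps, 1.0 - eps)
    sqrt_tau = np.sqrt(scales)
    X = np.column_stack([sqrt_tau, 1.0 / sqrt_tau])
    au = np.zeros(len(node_sets))
    bp = np.zeros(len(node_sets))
    tau1 = int(np.argmin(np.abs(scales - 1.0)))
    for j in range(len(node_sets)):
        if counts[:, j].sum() == 0:
            continue  # never recovered: support 0
        # only scales where the frequency is informative constrain the
        # probit curve; fully saturated scales sit at the clamp and would
        # flatten the fit
        informative = (counts[:, j] > 0) & (counts[:, j] < reps)
        if informative.sum() < 2:
            # (near-)always or (near-)never recovered: the extrapolation is
            # degenerate and the frequency at τ = 1 is the honest support
            au[j] = bp[j] = counts[tau1, j] / reps
            continue
        z = norm.ppf(1.0 - bp_tau[informative, j])
        # pvclust-style WLS weights: binomial variance mapped through the probit
        var = bp_tau[informative, j] * (1.0 - bp_tau[informative, j]) / (
            reps * norm.pdf(norm.ppf(bp_tau[informative, j])) ** 2)
        w = 1.0 / np.maximum(var, 1e-12)
        Xi = X[informative]
        WX = Xi * w[:, None]
        beta = np.linalg.solve(Xi.T @ WX, WX.T @ z)
        v, c = beta
        au[j] = 1.0 - norm.cdf(v - c)
        bp[j] = 1.0 - norm.cdf(v + c)
    tree.au = au
    tree.bp = bp
    return tree


# ---------------------------------------------------------------------------
# patient-removal stability


def _pair_clusters(reference: SubgroupAssignment,
                   new: SubgroupAssignment) -> dict[int, int]:
    """Greedy majority-overlap pairing new → reference (each used once).

    Ties broken by larger reference-cluster size, then lower label order.
    """
    ref_sizes = {l: len(reference.members(l)) for l in range(1, reference.k + 1)}
    overlaps = []
    for nl in range(1, new.k + 1):
        nm = new.members(nl)
        for rl in range(1, reference.k + 1):
            ov = len(nm & reference.members(rl))
            overlaps.append((ov, ref_sizes[rl], -rl, -nl, rl, nl))
    overlaps.sort(reverse=True)
    used_new: set[int] = set()
    used_ref: set[int] = set()
    pairing: dict[int, int] = {}
    for ov, _, _, _, rl, nl in overlaps:
        if nl in used_new or rl in used_ref:
            continue
        pairing[nl] = rl
        used_new.add(nl)
        used_ref.add(rl)
    return pairing


def removal_stability(matrix: ExpressionMatrix,
                      reference: SubgroupAssignment,
                      n_remove: int,
                      n_reps: int = 100,
                      tumor_samples: list[str] | None = None,
                      genes=None,
                      seed: int | None = None) -> dict:
    """Re-clustering correctness under random removal of tumor samples.

    Per replicate, ``n_remove`` tumor samples are dropped, the remaining
    samples re-clustered (k as in the reference), new clusters paired to the
    reference by majority overlap, and correctness = fraction of retained
    samples whose paired label matches their reference label.  Returns the
    per-replicate correctness values and their median.
    """
    all_samples = matrix.sample_ids
    if tumor_samples is None:
        tumor_samples = all_samples
    tumor_samples = [s for s in tumor_samples if s in set(all_samples)]
    if n_remove < 0 or n_remove >= len(tumor_samples):
        raise ValueError("n_remove out of range")
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_reps):
        if n_remove:
            drop = set(rng.choice(tumor_samples, size=n_remove, replace=False))
        else:
            drop = set()
        retained = [s for s in all_samples if s not in drop]
        sub = matrix.subset_samples(retained)
        new = cut_tree(cluster_samples(sub, genes=genes), reference.k)
        pairing = _pair_clusters(reference, new)
        correct = sum(
            1 for s in retained
            if pairing.get(new.labels[s]) == reference.labels[s]
        )
        values.append(correct / len(retained))
    values = np.asarray(values)
    return {"correctness": values, "median": float(np.median(values))}
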