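"""Synthetic T-PLL-like cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: three tumor subgroups plus a control group, with SG2 and SG3 closer
to each other than to SG1 (induced by a shared shift block); shared and
subgroup-specific differential genes on log2 scale with Gaussian noise;
segmental copy-number alterations with per-subgroup penetrance, partially
coupled to cis expression; a sparse hub-regulator network propagated into
target expression; and exponential survival with a sex-specific hazard and
independent censoring.

Default group sizes mirror the reference cohort (10 controls, 18/11/39
tumors); the gene count defaults to 2,000 for desk-scale runtimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix


@dataclass
class CNSegmentSpec:
    chrom: str
    start: int
    end: int
    log_ratio: float
    subgroups: tuple[str, ...]
    penetrance: float


def _default_segments() -> list[CNSegmentSpec]:
    return [
        CNSegmentSpec("chr8", 5_000_000, 40_000_000, -0.5,
                      ("SG1", "SG2", "SG3"), 0.7),
        CNSegmentSpec("chr8", 60_000_000, 95_000_000, 0.5,
                      ("SG1", "SG3"), 0.8),
        CNSegmentSpec("chr11", 60_000_000, 95_000_000, -0.5,
                      ("SG2", "SG3"), 0.6),
        CNSegmentSpec("chr14", 50_000_000, 90_000_000, 0.4,
                      ("SG1",), 0.7),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the package's reference
    study conditions."""

    n_genes: int = 2000
    n_control: int = 10
    n_sg1: int = 18
    n_sg2: int = 11
    n_sg3: int = 39
    base_mean_loc: float = 7.0
    base_mean_scale: float = 1.5
    noise_sd: float = 0.5
    # differential structure (log2 shifts; sign is negative w.p. down_fraction)
    shared_fraction: float = 0.05
    shared_shift: float = 1.5
    specific_fraction: float = 0.03
    subgroup_shift: float = 1.5
    close_fraction: float = 0.05
    delta_close: float = 1.2
    down_fraction: float = 0.6
    # copy number
    chromosomes: dict = field(default_factory=lambda: {
        "chr1": 100_000_000, "chr8": 100_000_000,
        "chr11": 100_000_000, "chr14": 100_000_000,
    })
    probes_per_chromosome: int = 150
    cn_segments: list = field(default_factory=_default_segments)
    cn_noise_sd: float = 0.15
    kappa: float = 0.3
    # hub network: modules of two co-regulating hubs sharing a target pool;
    # hubs carry an extra "activity" variance component that their targets
    # inherit, which is what makes the links identifiable
    n_hubs: int = 4
    targets_per_hub: int = 8
    weight_range: tuple[float, float] = (0.6, 1.0)
    hub_activity_sd: float = 1.2
    # survival (per-day hazards)
    baseline_hazard: float = 1.0 / 1000.0
    female_hazard_ratio: float = 2.0
    censoring_hazard: float = 1.0 / 2000.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("shared_fraction", "specific_fraction", "close_fraction",
                     "down_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_control", "n_sg1", "n_sg2", "n_sg3"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.n_hubs % 2 != 0:
            raise ValueError("n_hubs must be even (hubs work in pairs)")
        for frac, shift in (("shared_fraction", "shared_shift"),
                            ("specific_fraction", "subgroup_shift"),
                            ("close_fraction", "delta_close")):
            if getattr(self, frac) == 0.0 and getattr(self, shift) != 0.0:
                raise ValueError(
                    f"degenerate config: {frac} = 0 with nonzero {shift}")
        by_chrom: dict[str, list[CNSegmentSpec]] = {}
        for seg in self.cn_segments:
            if seg.chrom not in self.chromosomes:
                raise ValueError(f"segment on undeclared chromosome {seg.chrom}")
            if seg.end > self.chromosomes[seg.chrom] or seg.start < 0:
                raise ValueError(f"segment outside {seg.chrom} length")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs[:-1], segs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping segments on {chrom}")


@dataclass
class GroundTruth:
    labels: dict[str, str]
    sexes: dict[str, str]
    de_shifts: pd.DataFrame          # gene × subgroup planted log2 shift
    expected_shifts: pd.DataFrame    # planted + network-inherited + CN-driven
    gene_coords: pd.DataFrame        # gene_id, chrom, start, end
    segment_specs: list
    carriers: dict                   # (spec index) -> set of carrier samples
    gene_cn: pd.DataFrame            # gene × tumor-sample true segment value
    network_edges: list              # (hub, target, weight)
    seed: int


def _gene_coords(config: SimulationConfig) -> pd.DataFrame:
    chroms = list(config.chromosomes)
    rows = []
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        slot = i // len(chroms)
        per_chrom = int(np.ceil(config.n_genes / len(chroms)))
        length = config.chromosomes[chrom]
        start = int((slot + 0.5) / per_chrom * length)
        rows.append({"gene_id": f"G{i:04d}", "chrom": chrom,
                     "start": start, "end": start + 10_000})
    return pd.DataFrame(rows)


def generate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None):
    """Generate (ExpressionMatrix, SampleTable, GroundTruth).

    Expression = per-gene baseline + group shifts + hub-network propagation
    + cis copy-number coupling + Gaussian noise.  Fully reproducible from
    (config, seed); ``seed`` overrides ``config.seed`` when given.
    """
    config = config or SimulationConfig()
    config.validate()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    samples, labels = [], {}
    for i in range(config.n_control):
        sid = f"C{i + 1:03d}"
        samples.append(sid)
        labels[sid] = "control"
    t = 0
    for sg, n in (("SG1", config.n_sg1), ("SG2", config.n_sg2),
                  ("SG3", config.n_sg3)):
        for _ in range(n):
            t += 1
            sid = f"TP{t:03d}"
            samples.append(sid)
            labels[sid] = sg
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    coords = _gene_coords(config)

    base = rng.normal(config.base_mean_loc, config.base_mean_scale,
                      size=config.n_genes)
    expr = base[:, None] + rng.normal(0.0, config.noise_sd,
                                      size=(config.n_genes, len(samples)))
    expr = pd.DataFrame(expr, index=genes, columns=samples)

    # --- differential blocks (disjoint) -----------------------------------
    n_shared = int(round(config.shared_fraction * config.n_genes))
    n_close = int(round(config.close_fraction * config.n_genes))
    n_spec = int(round(config.specific_fraction * config.n_genes))
    perm = rng.permutation(config.n_genes)
    cursor = 0

    def take(k):
        nonlocal cursor
        block = perm[cursor:cursor + k]
        cursor += k
        return [genes[i] for i in block]

    shared_genes = take(n_shared)
    close_genes = take(n_close)
    spec_genes = {sg: take(n_spec) for sg in ("SG1", "SG2", "SG3")}

    shifts = pd.DataFrame(0.0, index=genes, columns=["SG1", "SG2", "SG3"])

    def signed(magnitude, size):
        sign = np.where(rng.random(size) < config.down_fraction, -1.0, 1.0)
        return sign * magnitude

    s = signed(config.shared_shift, len(shared_genes))
    for sg in ("SG1", "SG2", "SG3"):
        shifts.loc[shared_genes, sg] = s
    c = signed(config.delta_close, len(close_genes))
    for sg in ("SG2", "SG3"):
        shifts.loc[close_genes, sg] = c
    for sg in ("SG1", "SG2", "SG3"):
        shifts.loc[spec_genes[sg], sg] += signed(config.subgroup_shift,
                                                 len(spec_genes[sg]))
    for sg in ("SG1", "SG2", "SG3"):
        cols = [sid for sid in samples if labels[sid] == sg]
        expr[cols] = expr[cols].add(shifts[sg], axis=0)

    # --- hub network propagation ------------------------------------------
    # the subgroup-vs-control contrast a target inherits from its hub is
    # exactly w * hub_shift (the global centering drops out of the contrast)
    edges: list[tuple[str, str, float]] = []
    inherited = pd.DataFrame(0.0, index=genes, columns=["SG1", "SG2", "SG3"])
    de_pool = shared_genes + close_genes + sum(spec_genes.values(), [])
    if config.n_hubs >= 2 and len(de_pool) > config.n_hubs:
        hub_source = close_genes if len(close_genes) >= config.n_hubs else de_pool
        hubs = list(rng.choice(hub_source, size=config.n_hubs, replace=False))
        for hub in hubs:  # sample-specific regulator activity
            expr.loc[hub] = expr.loc[hub] + rng.normal(
                0.0, config.hub_activity_sd, size=len(samples))
        candidates = [g for g in de_pool if g not in set(hubs)]
        rng.shuffle(candidates)
        ci = 0
        for m in range(config.n_hubs // 2):
            pair = hubs[2 * m: 2 * m + 2]
            devs = {h: expr.loc[h] - expr.loc[h].mean() for h in pair}
            for _ in range(config.targets_per_hub):
                if ci >= len(candidates):
                    break
                target = candidates[ci]
                ci += 1
                for h in pair:
                    w = float(rng.uniform(*config.weight_range))
                    expr.loc[target] = expr.loc[target] + w * devs[h]
                    inherited.loc[target] += w * shifts.loc[h]
                    edges.append((h, target, w))

    # --- copy number + cis coupling ---------------------------------------
    tumor_samples = [sid for sid in samples if labels[sid] != "control"]
    carriers: dict[int, set] = {}
    gene_cn = pd.DataFrame(0.0, index=genes, columns=tumor_samples)
    mids = ((coords["start"] + coords["end"]) / 2.0).to_numpy()
    for si, spec in enumerate(config.cn_segments):
        in_seg = ((coords["chrom"] == spec.chrom).to_numpy()
                  & (mids >= spec.start) & (mids <= spec.end))
        seg_genes = coords.loc[in_seg, "gene_id"].to_numpy()
        carriers[si] = set()
        for sid in tumor_samples:
            if labels[sid] in spec.subgroups and rng.random() < spec.penetrance:
                carriers[si].add(sid)
                gene_cn.loc[seg_genes, sid] = spec.log_ratio
    cn_shift = pd.DataFrame(0.0, index=genes, columns=["SG1", "SG2", "SG3"])
    if config.kappa != 0.0:
        expr[tumor_samples] = expr[tumor_samples] + config.kappa * gene_cn
        for sg in ("SG1", "SG2", "SG3"):
            cols = [s for s in tumor_samples if labels[s] == sg]
            cn_shift[sg] = config.kappa * gene_cn[cols].mean(axis=1)
    expected = shifts + inherited + cn_shift

    # --- metadata + survival ----------------------------------------------
    sexes = {sid: ("female" if rng.random() < 0.5 else "male")
             for sid in samples}
    times, statuses = generate_survival(config, labels, sexes, rng=rng)
    meta = pd.DataFrame({
        "sample_id": samples,
        "group": [labels[s] for s in samples],
        "sex": [sexes[s] for s in samples],
        "age_years": np.round(rng.uniform(40, 80, size=len(samples))).astype(int),
        "pretreated": [("yes" if rng.random() < 0.2 else "no")
                       if labels[s] != "control" else "no" for s in samples],
        "stage": ["active" if labels[s] != "control" else "" for s in samples],
        "tcl1a_status": ["positive" if labels[s] != "control" else ""
                         for s in samples],
        "time_days": [times.get(s, np.nan) for s in samples],
        "status": [statuses.get(s, np.nan) for s in samples],
    }).set_index("sample_id", drop=False)

    truth = GroundTruth(
        labels=labels, sexes=sexes, de_shifts=shifts,
        expected_shifts=expected, gene_coords=coords,
        segment_specs=list(config.cn_segments), carriers=carriers,
        gene_cn=gene_cn, network_edges=edges, seed=config.seed,
    )
    return ExpressionMatrix(expr), meta, truth


def asdict_config(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["cn_segments"] = config.cn_segments
    return d


def generate_copy_number(config: SimulationConfig, truth: GroundTruth,
                         rng: np.random.Generator | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe-level log-ratio table for the cohort's tumor samples.

    Probe log-ratio = segment value (for carriers) + Gaussian noise; the
    carrier sets come from the ground truth so the probe data are consistent
    with the gene-level truth and the cis-coupled expression."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    tumor_samples = [s for s, l in truth.labels.items() if l != "control"]
    rows = []
    for chrom, length in config.chromosomes.items():
        n = config.probes_per_chromosome
        pos = np.linspace(length / (n + 1), length * n / (n + 1), n).astype(int)
        level = np.zeros((len(tumor_samples), n))
        for si, spec in enumerate(config.cn_segments):
            if spec.chrom != chrom:
                continue
            in_seg = (pos >= spec.start) & (pos <= spec.end)
            for j, sid in enumerate(tumor_samples):
                if sid in truth.carriers.get(si, set()):
                    level[j, in_seg] = spec.log_ratio
        noise = rng.normal(0.0, config.cn_noise_sd,
                           size=(len(tumor_samples), n))
        vals = level + noise
        for j, sid in enumerate(tumor_samples):
            for k in range(n):
                rows.append((sid, chrom, int(pos[k]), vals[j, k]))
    probes = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos",
                                         "log2ratio"])
    return probes, truth.gene_coords.copy()


def generate_survival(config: SimulationConfig, labels: dict, sexes: dict,
                      rng: np.random.Generator | None = None
                      ) -> tuple[dict, dict]:
    """Exponential event times with a sex hazard ratio and independent
    exponential censoring, for tumor samples only."""
    if config.baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    times, statuses = {}, {}
    for sid, lab in labels.items():
        if lab == "control":
            continue
        h = config.baseline_hazard
        if sexes.get(sid) == "female":
            h *= config.female_hazard_ratio
        t_event = rng.exponential(1.0 / h)
        if config.censoring_hazard > 0:
            t_cens = rng.exponential(1.0 / config.censoring_hazard)
        else:
            t_cens = np.inf
        if t_event <= t_cens:
            times[sid] = float(np.round(t_event, 1))
            statuses[sid] = "died"
        else:
            times[sid] = float(np.round(t_cens, 1))
            statuses[sid] = "censored"
    return times, statuses
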