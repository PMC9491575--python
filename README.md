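# tpll-subtyper

Expression-based subgroup discovery and molecular characterization for
T-cell prolymphocytic leukemia (T-PLL) cohorts — and, more generally, for
any small tumor-vs-control expression study with paired copy-number data.

T-PLL is a rare, aggressive mature T-cell leukemia.  Bulk expression
profiles of such cohorts (tens of patients, ~18k genes on log2 scale)
carry subtype structure that standard single-gene analyses miss.  This
package implements the full discovery pipeline as a tested library plus a
thin CLI:

1. **Subgroup discovery** — hierarchical clustering of samples under the
   correlation distance *d(i,j) = 1 − r(i,j)* with Ward's ward.D2 linkage;
   cluster support from the multiscale gene bootstrap (approximately
   unbiased AU p-values via probit extrapolation over resample sizes) and
   from patient-removal stability (re-cluster after dropping random tumor
   samples, re-pair clusters by majority overlap).
2. **Differential expression** — per-gene one-way linear models
   (subgroups vs control) with empirical-Bayes variance moderation: the
   posterior variance s̃² = (d₀·s₀² + d·s²)/(d₀ + d) feeds a moderated t
   with d₀ + d degrees of freedom; q-values by Benjamini–Hochberg.
3. **Enrichment** — direction-stratified over-representation of GMT
   categories by one-sided Fisher tests, BH-adjusted within category
   families.
4. **Copy number** — circular binary segmentation (CBS) of probe
   log2-ratios with permutation acceptance, gene-level assignment by the
   segment containing the gene midpoint, and per-subgroup median profiles.
5. **Regulatory networks** — each gene modeled as a lasso-sparse linear
   combination of its own copy number and the other differential genes;
   predictor entry scored by the covariance test (T_k ~ Exp(1) under the
   null, p = e^(−T_k)), links kept at a network-wide BH q ≤ 0.01, the whole
   inference repeated over 100 random 2/3 training subsets; consensus links
   (support ≥ 75) form modules (every gene ≥ 2 links, module ≥ 3 genes);
   prediction quality is benchmarked against degree-preserving null
   rewirings.
6. **Cross-cohort transfer** — parametric empirical-Bayes batch adjustment
   of a new cohort onto the reference, then nearest-positive-correlation
   label assignment.
7. **Survival** — Kaplan–Meier curves and log-rank tests by subgroup and
   by sex.
8. **Synthetic cohorts** — a generator that plants all of the above
   structure (subgroup hierarchy, shared/specific differential blocks,
   segmental copy-number alterations with cis coupling, hub-regulator
   modules, exponential survival with censoring) with full ground truth,
   so every stage is testable without any external data.

## Worked example

```python
from tpll_subtyper.synthetic_data import SimulationConfig, generate_cohort
from tpll_subtyper import subgroup_discovery as sd, diffexpr
from tpll_subtyper.stats_core import fisher_exact_rxc

matrix, meta, truth = generate_cohort(SimulationConfig(), seed=1)
tree = sd.cluster_samples(matrix)                 # 1-r distance + ward.D2
assign = sd.cut_tree(tree, 4)
stab = sd.removal_stability(
    matrix, assign, n_remove=10, n_reps=100,
    tumor_samples=[s for s, l in truth.labels.items() if l != "control"],
    seed=2)
res = diffexpr.differential_expression(matrix, meta["group"])
```

prints, with the numbers the code actually produces:

```
cohort: 2000 genes x 78 samples
cluster sizes: {1: 11, 2: 39, 3: 10, 4: 18}
median removal-stability correctness: 100.0%
SG1: 166 differential genes at q <= 0.05
SG2: 272 differential genes at q <= 0.05
SG3: 272 differential genes at q <= 0.05
```

The four clusters recover the planted groups exactly (10 controls and
tumor subgroups of 18/11/39), and the clustering re-assigns every retained
sample correctly in the median replicate even after removing ten patients.
A clinical side check: the exact r×c test on pretreated-vs-untreated counts
per subgroup `[[4,14],[1,10],[7,32]]` gives p = 0.75 — pretreatment does
not differ between subgroups.

The same stages are available from the shell:

```sh
tpll-subtyper run-all --seed 7 --out runs/demo        # simulate + all stages
tpll-subtyper cluster --expr expr.tsv --k 4 --out out/
tpll-subtyper de --expr expr.tsv --meta meta.tsv --out out/
```

## Layout

```
src/tpll_subtyper/
  core_io.py             TSV/GMT/metadata readers + validated containers
  synthetic_data.py      ground-truth cohort generator
  stats_core.py          BH, exact r×c Fisher, Wilcoxon tests
  subgroup_discovery.py  distance, Ward tree, AU bootstrap, removal stability
  diffexpr.py            moderated-t differential expression
  enrichment.py          category over-representation
  copy_number.py         CBS segmentation, gene mapping, profiles
  network.py             ensemble lasso networks, consensus modules
  classify.py            batch adjustment + label transfer
  survival.py            Kaplan–Meier / log-rank
  cli.py                 `tpll-subtyper` command group
docs/methods.md          model and design notes
```
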