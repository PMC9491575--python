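# Methods and design notes

This note documents the models behind each stage, the tunable parameters
and their defaults, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Subgroup discovery

Samples are compared by the correlation distance d(i,j) = 1 − r(i,j),
with r the Pearson correlation of the two samples' log2 expression
profiles across all genes (or a supplied subset, e.g. the differential
union).  The distance is in [0, 2] and invariant to per-sample affine
transforms with positive scale.  Agglomeration uses Ward's ward.D2
criterion — scipy's `linkage(method="ward")` applied to the raw
dissimilarities, which implements the Lance–Williams recurrence on squared
input distances.  Tie behavior follows scipy's deterministic nearest-
neighbor chain; determinism given input order is the contract, not
bit-equality with any other implementation.  `cut_tree(k)` removes the
k − 1 highest merges; cluster labels are numbered by dendrogram
left-to-right order so runs are comparable.  k defaults to 4 (one control
cluster plus three tumor subgroups) and is always explicit — there is no
automatic model selection.

**Multiscale bootstrap (AU support).**  Genes are resampled with
replacement at relative sizes τ ∈ {0.5, 0.6, …, 1.4} (ten scales), with
the total run count (default 10,000) split evenly across scales.  For each
internal node of the reference tree the bootstrap frequency BP_τ is
recorded, clamped to (ε, 1 − ε) with ε = 1/(2·reps) before the probit
transform, and the curve z_τ = Φ⁻¹(1 − BP_τ) = v·√τ + c/√τ is fitted by
weighted least squares with binomial-variance weights mapped through the
probit.  AU = 1 − Φ(v − c) and BP = 1 − Φ(v + c); AU = BP when the fitted
curvature c is zero.  Two degenerate regimes are handled explicitly:
nodes never re-observed get support 0, and nodes whose frequency is
saturated (0 or reps) at all but one scale cannot constrain the
extrapolation, so the frequency at τ = 1 is reported for both AU and BP
instead of a meaningless fit.

**Removal stability.**  Per replicate, `n_remove` tumor samples are
dropped uniformly at random, the remaining samples re-clustered and cut at
the reference k, and new clusters paired to reference clusters greedily by
descending overlap count (each cluster used once; ties broken by larger
reference-cluster size, then lower label order).  Correctness is the
fraction of retained samples whose paired label matches their reference
label; the median over replicates is the headline statistic that
`scripts/acceptance.py` recomputes (100 replicates, n_remove = 10).

## Differential expression

A one-way four-group linear model per gene (control baseline, no
covariates) gives contrasts β̂ = mean(SG) − mean(control) and a single
pooled residual variance s² on d = n − 4 degrees of freedom.  One joint
model (rather than three separate two-group fits) was chosen so all
contrasts share one variance estimate; the per-contrast functions accept
any group coding, so the alternative is a caller-side choice.

Variance moderation treats s² as scaled-χ²_d around a gene-level σ² drawn
from a scaled-inverse-χ² prior (d₀, s₀²).  Hyperparameters are estimated
by moment matching on z = log s²: the excess variance of z over the
sampling term ψ′(d/2) equals ψ′(d₀/2), solved by Newton inversion of the
trigamma function; non-positive excess yields d₀ = ∞ (full shrinkage), and
an exactly constant set of variances returns that common value as s₀².
The moderated t uses s̃² = (d₀s₀² + d·s²)/(d₀ + d) with d₀ + d degrees of
freedom (normal tail at d₀ = ∞).  Genes are called differential at
BH q ≤ 0.05 per contrast; direction is the sign of β̂.

## Enrichment

One-sided (over-representation) Fisher tests on the 2×2 table of
(in-category × differential) counts, per direction.  The background is the
set of measured genes, not the genome — counts are platform-relative.
A two-sided switch exists.  BH families are the category families
(signaling / metabolic / gene-class, from separate GMT files), adjusted
separately per direction.  Categories with empty background intersection
report p = 1 rather than being dropped.

## Copy-number segmentation

CBS maximizes the two-sample t statistic over all circular arcs (i, j] of
the current segment (both arc and complement at least `min_width` = 2
probes) and accepts the split when the permutation p-value — re-computing
the maximal statistic on shuffles of the segment's probe order — is at
most `alpha` = 0.01 with `n_perm` = 1,000 permutations by default.
Accepted splits recurse into up to three subsegments.  Permutations are
evaluated vectorized in batches with early stopping as soon as
non-significance is guaranteed, which makes flat segments cheap.  There is
no smoothing or split-undo step.  Genes take the mean log-ratio of the
segment containing their midpoint; a midpoint exactly on a segment end
goes to the lower-coordinate segment; genes on chromosomes without probes
are NA.  Coordinates are 1-based inclusive throughout.  Chromosome X is
treated like the autosomes; sex-linked dosage shows up in reports rather
than being corrected away.

## Network inference

For each target gene, the response is its centered training expression;
predictors are the z-scored expression of every other gene in the
universe (by default the differential union) plus the target's own
z-scored gene-level copy number.  The lasso entry path (LARS) is limited
to `max_steps` = 10 knots — models beyond ten stable predictors are not
interpretable at these sample sizes.  Each entering predictor is scored by
the covariance test T_k = (⟨y, Xβ̂(λ_{k+1})⟩ − ⟨y, X_A β̃_A(λ_{k+1})⟩)/σ̂²
with p = exp(−T_k); σ̂² is the df-corrected residual variance of the OLS
refit on the active set at the λ chosen by 10-fold cross-validation over
the path knots.  This σ̂² construction is the package's own documented
choice, isolated behind one function.  BH runs per network across all
tested links of all genes; links retained at q ≤ 0.01 are refit jointly by
least squares on the raw training data.

The inference repeats over `n_runs` = 100 uniform random training subsets
of size round(2n/3) (e.g. 35 of 53 paired samples).  A link between two
genes counts as present in a run if retained in either direction; links
present in ≥ 75 runs form the consensus graph.  Modules are connected
components iteratively pruned of genes with fewer than two internal links,
kept at three or more genes; the pruning rule has a unique fixed point, so
extraction is order-independent.  Link sign is the majority coefficient
sign across supporting run-directions; negative links are retained in all
outputs.  Prediction quality is the per-gene Pearson correlation between
predicted and observed expression on each run's held-out third, averaged
over runs; the baseline is the same quantity for degree-preserving
rewirings (repeated pair swaps keeping every gene's out- and in-degree,
coefficients refit by least squares), compared by the paired Wilcoxon
signed-rank test.

## Cross-cohort transfer

Parametric empirical-Bayes batch adjustment without covariates: genes are
standardized by the pooled two-batch fit, per-batch location (γ) and scale
(δ) effects are shrunk toward moment-estimated priors (normal for γ,
inverse-gamma for δ) by the usual fixed-point iteration to 1e-4, and data
are back-transformed.  Genes are intersected *before* adjustment (joint
standardization requires a common gene space; minimum overlap 500 genes).
Each incoming sample takes the subgroup label of the reference sample
with the strongest positive correlation; a non-positive best correlation
is "unassignable" and a best correlation below 0.2 is flagged
low-confidence rather than silently assigned — low-purity samples
correlate best with controls, and surfacing that is more useful than
hiding it.

## Survival

Kaplan–Meier product-limit estimation and the standard observed-vs-
expected log-rank χ² over pooled event times (lifelines underneath).
"Alive with disease" is non-informative censoring; at tied times deaths
precede censorings.  Times are days from diagnosis.  No Cox models.

## The synthetic-data generator

The generator emulates a microarray-style study: per-gene Gaussian
baselines (mean ~ N(7, 1.5²) log2 units) with noise sd 0.5, group sizes
10 controls / 18 SG1 / 11 SG2 / 39 SG3, and 2,000 genes by default (the
structure, not the gene count, is what the analyses depend on; 2,000 keeps
every test desk-scale).  Differential structure is planted as disjoint
blocks: 5% of genes shifted in all three subgroups, 3% per subgroup
specifically (|shift| = 1.5), and 5% shifted jointly in SG2 and SG3
(|shift| = 1.2) — this "close" block is what makes ((SG2, SG3), SG1) the
expected tree topology.  Signs are negative with probability 0.6,
mirroring the predominance of down-regulation in tumor-vs-control
contrasts.

Copy number uses four synthetic chromosomes (100 Mb, 150 probes each)
with default events: an 8p-like deletion (−0.5, all subgroups, penetrance
0.7), an 8q-like duplication (+0.5, SG1 and SG3 only, 0.8), an 11q-like
deletion (−0.5, SG2/SG3, 0.6) and a 14q-like duplication (+0.4, SG1,
0.7).  Carrier probes get the segment value plus N(0, 0.15) noise;
carriers' in-segment genes receive κ·log-ratio added to expression
(κ = 0.3), so cis-coupled genes are genuinely differential — the ground
truth therefore records both the planted shifts and the *expected* total
shift including copy-number and network contributions, and false-positive
accounting in the tests uses the latter.

The regulator network consists of modules of **two** co-regulating hubs
sharing a target pool (default 4 hubs → 2 modules, 8 targets per module,
weights U(0.6, 1.0)).  Hubs carry an extra "activity" component
(sd 1.2) that their targets inherit; this sample-specific variance is
what makes the links identifiable beyond mere group-pattern correlation,
and the two-hub design is what lets recovered modules survive the
"every gene ≥ 2 links" rule.  Survival times are exponential
(baseline hazard 1/1000 per day) with a female hazard ratio of 2 and
independent exponential censoring (1/2000 per day).

What the generator does **not** emulate: probe-level microarray artifacts,
RNA-seq counts, correlated noise between genes outside the planted
network, subclonal or allele-specific copy number, and non-proportional
hazards.  Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not performance on any real
cohort.

## Problem sizes used in the test suite

Tests run the full default cohort for clustering, differential expression
and stability checks, and a reduced cohort (400 genes, differential
universe ≈ 100 genes, 20 ensemble runs at support ≥ 15, 3 null rewirings)
for the network-recovery checks; null-calibration suites use 200–2,000
replicates as stated in each test.  These sizes are the package's own
desk-scale choices and are encoded in the tests themselves.

## Known limitations

* The AU extrapolation is unreliable for clusters at the resampling
  boundary (handled by the τ = 1 fallback, reported as such).
* The covariance-test null is asymptotic in the predictor count; at very
  small universes its p-values are conservative in the tail.
* CBS without an undo step can oversegment long noisy chromosomes at
  liberal alpha; the default alpha = 0.01 is deliberately strict.
* ComBat-style adjustment assumes the subgroup composition of the two
  cohorts is comparable; a cohort dominated by one subgroup will have part
  of its biology absorbed into the batch term.
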