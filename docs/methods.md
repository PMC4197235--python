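# Methods

This note documents the statistical models implemented in `heartnet`,
the defaults and why they were chosen, what the synthetic-data
generator emulates, and the numerical conventions used in corner cases.

## Study design and containers

An `ExpressionStudy` holds a log2 expression matrix (features ×
samples), a feature → gene-symbol map (many probes may map to one gene;
unannotated probes carry NaN), and per-sample condition/replicate
labels. The reference design is a replicated injury time course:
control plus 1/3/5/7 days post-injury, 3 replicates each (15 samples).
The first label in `condition_order` is the reference for all
contrasts. Missing entries (NaN) are allowed and handled pairwise;
infinities are rejected.

Gene-level analyses collapse probes by keeping, per gene, the probe
with the smallest omnibus raw p-value. This rule is deterministic,
favours the probe with the clearest signal, and is applied before all
network stages and cross-platform matching (which is case-insensitive
on the symbol).

## Moderated differential expression

Pre-filtering removes features whose maximum over all samples never
exceeds the expression floor (default 6 on the log2 scale) — weakly
expressed probes carry mostly noise at this sample size and removing
them increases testing power.

The model is a per-feature one-way fit of condition means. With
residual variance `s_g²` on `d_g` degrees of freedom, the
empirical-Bayes prior `(d0, s0²)` is estimated by fitting a scaled F
distribution to the `s_g²` via moments of `log s_g²`:
`e_g = log s_g² − ψ(d_g/2) + log(d_g/2)`, `d0 = 2·ψ₁⁻¹(var(e) −
mean ψ₁(d_g/2))`, `s0² = exp(mean(e) + ψ(d0/2) − log(d0/2))`, with
digamma ψ and trigamma ψ₁ (Newton inversion). A non-positive moment
estimate means the observed variances are consistent with a single
common value, and the fit falls back to complete pooling (`d0 = ∞`);
moderated t/F statistics then use normal/χ² reference distributions.
Posterior variances are `s̃_g² = (d0·s0² + d_g·s_g²)/(d0 + d_g)`;
moderated t per contrast uses `d0 + d_g` degrees of freedom, and the
omnibus moderated F spans the four non-control coefficients, using the
closed form `b'U⁻¹b = Σ n_c b_c² − (Σ n_c b_c)²/(n₀ + Σ n_c)` for the
one-way contrast covariance. Features with zero residual df or an
empty condition are excluded with a warning. FDR control is
Benjamini–Hochberg; both the omnibus count and the per-contrast counts
are reported, with the omnibus as the default definition of
"variable across time points".

The test suite checks the implementation against an independently
coded straight-line evaluation of these formulas (different root
finder, explicit loops) to 1e-10, and against the reference R
implementation of moderated statistics on a small fixture.

## Maximal information coefficient

MIC is the maximum over grid resolutions (a, b) with `a·b ≤ B(n)` of
the grid-optimised mutual information normalised by `log₂ min(a,b)`.
`B(n) = max(n^0.6, 4)`: the 0.6 exponent is the published default, and
the floor of 4 keeps the minimal informative 2×2 grid admissible at the
small n of replicated time courses (at n = 15 the 2×2 grid is the only
admissible resolution). For a fixed partition of one axis the optimal
contiguous partition of the other axis is found exactly by dynamic
programming over clump boundaries (the objective is column-additive);
the fixed axis is enumerated exhaustively while the number of
contiguous partitions stays within a budget (20 000 per grid — always
the case for n up to a few dozen), and otherwise falls back to the
standard equipartition heuristic. Both orientations are searched. The
implementation is therefore exact at this package's sample sizes, and
the suite verifies exact agreement with a brute-force enumeration of
every admissible grid for n ≤ 10. Constant vectors score 0; MIC
depends only on value order, so it is invariant to strictly monotone
transforms. Note that MIC = 1 on noiseless monotone data requires a
balanced 2×2 split and hence an even n at these grid sizes; at n = 15
the maximum achievable is H(7/15) ≈ 0.997.

## Co-expression network

Edges among the top differentially expressed genes (default FDR ≤
1e-4) require `|r| ≥ 0.95` — boundary kept, following "filter out
|r| < 0.95" semantics — and `MIC > 0.95` (strict, as stated). MIC is
evaluated only on pairs that pass the correlation filter. Correlations
use pairwise-complete observations; constant genes have undefined
coefficients and contribute no edges. Isolated nodes are dropped from
the reported network, which is exported as SIF and GraphML with r, MIC
and optional per-condition log2FC node annotations.

## Cohesive overlapping modules

Cohesiveness of a vertex set V is `f(V) = w_in/(w_in + w_bound +
p·|V|)` with penalty p = 2 and unit edge weights in unweighted mode.
Seeds are processed in decreasing-degree order (lexicographic
tie-break); a node already inside a grown cluster is not reused as a
seed. Growth applies the single addition (of a boundary vertex) or
removal that most increases f, until no step improves it — so each
accepted step strictly increases cohesiveness and every reported
module is a local optimum. Clusters with match score `ω(A,B) =
|A∩B|²/(|A||B|) ≥ 0.8` are merged to a fixed point (highest ω first).
Modules below 5 nodes or density 0.5 ("auto" for unweighted networks)
are discarded; the haircut parameter defaults to 0 (a no-op, retained
for fidelity). Module quality is the one-sided Mann–Whitney U p
comparing, over boundary vertices, in-module versus out-of-module
incident edge weight; a module without boundary vertices has no
defined p (reported as missing), and a module whose boundary shows no
in/out separation yields a large one-sided p.

## Model-tree directed network

Each target gene is modelled from the remaining genes by a
piecewise-linear model tree in the M5 family: splits maximise the
standard-deviation reduction `SDR = sd(T) − Σ |T_i|/|T|·sd(T_i)`,
stopping when a node's sd falls below 5% of the root sd or the node
has fewer than twice the minimum leaf size (4). Node models use the
predictors appearing in splits of the subtree, with greedy backward
attribute elimination under the `(n+ν)/(n−ν)`-adjusted mean absolute
error. Pruning replaces a subtree by its node model whenever the
model's adjusted error does not exceed the subtree's, where the
subtree's factor counts every parameter below it (leaf coefficients,
intercepts and split thresholds) — this is what makes a target with no
real predictors collapse to a single constant leaf. Predictions are
smoothed along the root path with the classic constant k = 15.

The tree's relative error is mean absolute prediction error divided by
the target's mean absolute deviation from its mean (0 for a
zero-variance target; 1 for a constant-mean prediction). Targets above
θ = 0.30 contribute no edges. For each retained (predictor, target)
pair the dependency significance is the two-sided correlation t-test
with n−2 df — chosen as the simplest test of a global linear
dependency, isolated in one function so a coefficient Wald test could
be swapped in — and the family is Benjamini–Yekutieli adjusted
(step-up with harmonic correction `c(m) = Σ 1/i`, valid under the
arbitrary dependence of co-expression data), kept at α = 0.05. Edges
point predictor → target; the UP/DOWN label is the dependency's sign,
and the reported slope is the size-weighted mean leaf coefficient.
Global (all-sample) dependencies are tested; leaf-local testing is a
possible variant not implemented.

Two behaviours of this family are worth knowing. First, SDR measures
variance reduction in the target, so a changepoint between regimes
whose target-value distributions coincide (e.g. a symmetric tent) is
invisible to the split criterion. Second, among near-collinear
predictors (a hub and its dependents) the sparse leaf models keep
whichever single predictor fits marginally best, so an individual
dependency can occasionally be attributed to a sibling rather than the
hub; recovery of a planted 4-edge signed hub is therefore expected in
most but not all replicates.

## Weighted topological-overlap modules

Adjacency is `a_ij = |cor(x_i, x_j)|^β` with β = 10 and Spearman
correlation on pairwise-complete observations (Pearson available);
constant genes get zero adjacency, and the diagonal is zero for
connectivity sums. The topological overlap is
`TOM_ij = (Σ_u a_iu·a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
`TOM_ii = 1`, applied to any symmetric matrix with entries in [0, 1]
(pairwise-complete correlation matrices need not be positive
definite; the formula does not care). Genes are clustered by
average-linkage on 1 − TOM. The dynamic hybrid cut is implemented in
a reduced, documented form: a static cut of the dendrogram at height
0.99, branches of at least `min_module_size` (default 20) become
modules, and remaining genes join the nearest module by average TOM
distance when within the cut height (else label 0, unassigned). The
published core-scatter branch evaluation is omitted; this reduction is
deterministic and recovers planted blocks, but exact reproduction of
module sizes from the original heuristic is not expected.

Module eigengenes are the first principal components (unit norm) of
the standardised module submatrices, sign-oriented to correlate
positively with the module's mean profile, since principal components
are sign-ambiguous and membership scores are reported signed. Modules
whose eigengenes have dissimilarity 1 − cor < 0.15 are merged
iteratively (closest pair first). Module membership is
`MM_g = cor(x_g, eigengene)` using the network's correlation type,
with p from the two-sided t-test on n−2 df. In unsigned networks
anti-correlated gene groups join one module and show MM of opposite
signs — the intended behaviour for hub/anti-hub circuits.

## Concordance

Between-dataset reproducibility uses per-gene Pearson correlation of
condition-mean profiles over the matched conditions (at least 3;
typically control and days 1/3/5). Condition means are used rather
than per-sample pairing because a second dataset generally has
unequal replication, which makes per-sample pairing ill-defined. Genes
with a flat profile in either study are excluded (undefined
correlation). Genes with r > 0.8 are called concordant; with 4-point
profiles the null rate of that threshold is appreciable (about 10%),
so the concordant list is a screen, not a test — the Monte-Carlo null
is part of the test suite. Fold-change concordance between two tables
at one condition is the Pearson r over paired per-gene log2FC values
(genes matched case-insensitively by symbol), with r² and the
correlation-test p.

## qPCR quantification

Technical duplicates are averaged on the Cq scale. Relative quantity
vs the calibrator condition is `RQ = E^(Cq_cal − Cq_sample)` with each
primer pair's own efficiency E (fold per cycle; 2 = 100%). Per
sample, the normalisation factor is the geometric mean of the three
reference-gene RQs (ef1a, rpl13a, tuba1); per gene and day,
`log2FC = mean log2(norm, injured) − mean log2(norm, sham)` over
biological replicates, with the standard error combining both arms'
replicate variability. Averaging technical replicates on the Cq scale
and biological replicates on the log2 normalised scale matches
standard ΔΔCq practice. A common template-amount change in a sample
cancels exactly through the normalisation for any mix of efficiencies
(the efficiency correction converts each gene's Cq shift back to the
same log2 amount); a common additive Cq shift cancels exactly when
efficiencies are equal, and only approximately otherwise.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume,
not the microarray measurement process: values are Gaussian on the
log2 scale (processed intensities, not counts), with per-gene
baselines N(9, 1).

- Differentially expressed genes receive per-condition offsets drawn
  N(0, effect_size_sd), default sd 2 log2 units; measurement noise is
  N(0, 0.3) per sample.
- Module genes follow `gene = baseline + profile(condition) +
  s·(√ρ·latent + √(1−ρ)·idiosyncratic)` with latent and idiosyncratic
  standard normal per sample and scale s (`module_signal_sd`), giving
  expected pairwise within-module correlation exactly ρ when the
  shared condition profile is flat (a non-flat profile raises it).
- The hub gene carries an optional condition profile (the central node
  of an injury-response circuit is itself injury-responsive) plus
  independent variation of sd 2 — the same scale as the planted
  differential effects; each dependent is `sign·magnitude` times the
  hub's centred signal plus residual noise.
- Multiple probes per gene share the gene signal plus independent
  probe noise (sd 0.1); the first probe reports the gene signal
  itself.
- Low-expressed features are capped below the expression floor.
- Concordant dataset pairs give every gene a random condition profile
  (sd 1); a planted fraction shares the profile across studies up to a
  perturbation sd, the rest draw independently; the second study may
  have fewer or unbalanced replicates.
- qPCR tables put `Cq = base_g − (log2 q + log2 m_s)/log2 E_g` plus
  noise, with condition-dependent quantity q, per-sample template
  loading m_s, per-primer efficiency, and duplicate technical
  measures.

A single seeded generator drives all draws, so identical
configurations produce bit-identical outputs. What passing recovery
tests on these data do **not** show: robustness to probe saturation,
batch or spatial artifacts, non-Gaussian heavy tails, outlier arrays,
or annotation errors — none of which are simulated.

## Pipeline, candidate selection and problem sizes

The pipeline runs: simulate (or load) → filter + moderated DE → top
genes (FDR ≤ 1e-4) → correlation+MIC network → cohesive modules →
model-tree network → weighted modules on the broader FDR < 0.05 set →
profile concordance against a companion dataset → candidate selection
→ optional qPCR validation of candidate fold changes. The companion
dataset for the concordance stage is generated as an independent
concordant pair: its role is to exercise the cross-dataset screen, so
its planted concordant genes are unrelated to the planted network
structure (as in real paired studies, where the concordance list and
the network hits need not overlap). Candidates are the union of genes
flagged by any enabled technique (cohesive-module member; directed
network node; |MM| ≥ 0.8 in a weighted module; cross-dataset
concordant), minus configured exclusions, plus configured manual
additions — inclusion criteria that rest on biological judgment
(functional novelty, primer quality) are config lists, never inferred
— ranked by omnibus FDR, then flag count. Stage outputs are pure
functions of (config, seed), and rerunning a config byte-identically
reproduces every output file.

Default simulation sizes keep every stage's behaviour visible while
the full demo runs in seconds: 300 genes (45 DE, two 30-gene modules
with time profiles at ρ = 0.95 and within-module scale 0.5, a 5-gene
hub circuit), 15 samples. Recovery measurements in the test suite and
the acceptance script use 10–20 replicates per condition: 2000-gene
nulls and 200-gene recovery runs for the DE stage, 45-node planted
partitions (within-density 0.9, between 0.02) for cohesive modules,
100-gene two-block designs (ρ = 0.9) for weighted modules, 10-gene hub
studies for the directed network, 100-gene concordant pairs, and
3-gene qPCR panels with Cq noise 0.2.

## Known limitations

- The dynamic-cut reduction and unsigned adjacency mean weighted
  module boundaries (and hence sizes) will differ from the full
  published heuristic on real data.
- The cohesive-module quality p-value follows the boundary-weight
  Mann–Whitney construction of the original tool's publication; the
  exact null used by the tool itself is not documented, so printed
  p-values are comparable only approximately.
- MIC above n ≈ 50 engages the equipartition heuristic for the larger
  grids and is then a lower bound, as in the published estimator.
- The model-tree network tests global linear dependencies; leaf-local
  (subspace) dependencies are extracted but not separately tested.
- No array normalisation, background correction or probe summarisation
  is performed: inputs are assumed to be processed log2 matrices.
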