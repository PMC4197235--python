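# heartnet

Network-based identification of genes with robust early transcriptional
responses to cardiac injury, built for zebrafish heart-regeneration
time-course expression data.

Adult zebrafish regenerate their myocardium after ventricular amputation
or cryoinjury, and the genes driving the early injury response are
candidate targets for boosting repair in mammals. Given a small
replicated time course of log2 expression (typically 5 conditions —
control and 1/3/5/7 days post-injury — with 3 replicates each),
`heartnet` asks which genes respond reproducibly, and which sit at the
centre of the co-expression structure of that response. Because single
techniques are fragile at n = 15, the package combines several
independent analyses and takes their union as the candidate set, then
scores reproducibility against independent datasets and qPCR.

## What it computes

1. **Moderated differential expression.** Features that never exceed
   log2 expression 6 are removed. A one-way condition-means model is fit
   per feature; residual variances `s_g²` (df `d_g`) are shrunk with the
   empirical-Bayes prior `(d₀, s₀²)` estimated by the method of moments
   on `log s_g²` (digamma/trigamma inversion), giving posterior
   variances `s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g)`, moderated t per
   timepoint-vs-control contrast and a moderated omnibus F, with
   Benjamini–Hochberg FDR control.
2. **Co-expression network.** Over the top-ranked genes (one probe per
   gene, smallest omnibus p), edges require `|r| ≥ 0.95` (Pearson) and a
   maximal information coefficient `MIC > 0.95` as a non-parametric
   confirmation. MIC maximises grid mutual information
   `I(P;Q)/log₂ min(a,b)` over grids with `a·b ≤ B(n)`.
3. **Cohesive overlapping modules.** Greedy growth of the cohesiveness
   `f(V) = w_in/(w_in + w_bound + p·|V|)` from unused high-degree seeds,
   merging of candidates with overlap `ω(A,B) = |A∩B|²/(|A||B|) ≥ 0.8`,
   size/density filtering, and a one-sided Mann–Whitney quality p-value
   comparing in- vs out-of-module edge weight over boundary vertices.
4. **Model-tree directed network.** Each gene in turn is the target of a
   piecewise-linear model tree (standard-deviation-reduction splits,
   adjusted-error pruning, smoothing). Targets with relative error
   > θ = 30% are discarded; each (predictor, target) dependency is
   tested by the correlation t-test, Benjamini–Yekutieli adjusted, and
   kept at α = 0.05 with its sign as the UP/DOWN edge label.
5. **Weighted topological-overlap modules.** Soft-thresholded adjacency
   `a_ij = |cor|^β` (β = 10, Spearman), TOM, average-linkage clustering
   of 1−TOM with a reduced dynamic cut, module eigengenes (first
   principal components), eigengene merging below 0.15 dissimilarity,
   and signed module membership `MM = cor(x_g, eigengene)`.
6. **Concordance and qPCR validation.** Per-gene Pearson correlation of
   condition-mean profiles across datasets (concordant at r > 0.8), and
   efficiency-corrected, triple-reference-gene-normalised ΔΔCq fold
   changes from Cq tables, compared to the array fold changes.

A synthetic-data generator produces studies with planted differential
expression, correlated modules, a signed hub circuit, concordant
dataset pairs and qPCR tables — with ground truth — so every stage is
testable by parameter recovery.

## Worked example

```python
from heartnet.pipeline import run_pipeline

outputs = run_pipeline({"seed": 1}, "runs/demo")
for line in outputs["log"][1:]:
    print(line)
```

prints (300 simulated genes: 45 planted differentially expressed genes,
two 30-gene co-expression modules with injury-time profiles, and a hub
with four signed dependents):

```
de: 300 features -> 300 after floor 6.0; d0=10.17 s02=0.1055
top genes (FDR<0.0001): 77
coexpr: 43 nodes, 418 edges (|r|>=0.95, MIC>0.95)
cohesive: 2 modules
treenet: 29 directed associations
weighted: 1 modules over 102 genes
concordance: 46 / 300 genes with r > 0.8
candidates: 97 genes
qpcr concordance at 1d: r=0.999 r2=0.998 p=4.82e-15
```

Reading the output: the moderated model finds 77 genes at FDR ≤ 1e-4;
the 0.95/0.95 correlation+MIC filter keeps a 43-node network in which
the two planted co-expression programmes surface as the 2 cohesive
modules; the model trees recover the hub circuit among 29 signed
directed associations; the two anti-correlated planted programmes merge
into one weighted module (unsigned networks join anti-correlated genes,
which then show membership scores of opposite sign); 46 genes pass the
cross-dataset profile concordance screen; and the simulated qPCR
validation reproduces the array fold changes at day 1 with r = 0.999.
The candidate table (`runs/demo/candidates.tsv`) flags each gene with
the technique(s) that selected it, ranked by omnibus FDR.

The same stages are exposed as a CLI (`heartnet simulate`, `de`,
`coexpr`, `cohesive`, `treenet`, `weighted`, `concord`, `qpcr`,
`candidates`, `run-all`).

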