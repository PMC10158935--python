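# Methods

This note records the models, parameter choices and numerical decisions
behind `cernet`, and what the synthetic benchmarks do and do not
demonstrate.

## Differential expression

The statistic is the moderated two-sample quantity
d = (x̄₁ − x̄₂) / (s + s₀) with s the pooled-variance standard error of the
mean difference, so at s₀ = 0 it reduces exactly to the pooled t statistic
(this identity is tested against an independent t computation). The
exchangeability constant s₀ damps the inflated d values of low-variance
features. We estimate s₀ as the **median of the per-feature standard
errors** — a deterministic, easily documented choice; the classical
percentile-search tuning adds complexity without changing behaviour on the
Gaussian cohorts used here.

Significance comes from label permutations applied jointly to all
features, with the add-one estimate p = (1 + #{|d*| ≥ |d|}) / (n_perm + 1)
so p is never 0. Default n_perm = 1000; the test suite and acceptance
script use 199–499 permutations, which bounds the attainable p at
1/200–1/500 — ample resolution for the 0.01 calling threshold.

Calling combines fold change and p with **"or" by default**: a feature is
differential when |log2FC| > threshold (1.0 for miRNA/mRNA, 0.58 for
lncRNA) *or* p < 0.01. An "or" between an effect-size and a significance
criterion is permissive and arguably unusual, so the combiner is an
explicit argument (`combine="and"` gives the conservative rule) rather
than a hidden constant. No multiple-testing correction is applied; the
thresholds are raw by design.

## Cohort preprocessing

Features missing in strictly more than 30% of samples are deleted
(boundary: exactly 30% is kept). Surviving gaps are imputed by the
feature's per-condition mean — deletion alone leaves undefined cells in
the correlation stage, and the per-condition mean is the least informative
completion that does not distort tumor/normal mean differences. Raw-scale
input is transformed as log2(x + 1); the pseudocount avoids −∞ at zero.
Preprocessing is idempotent on a clean matrix.

## Network construction

Edges require co-occurrence in an external candidate catalog *and* a
correlation criterion over **all samples (tumor + normal)**: Pearson
r < −0.7 (strict) for miRNA→target pairs, r > +0.7 (strict) for
lncRNA–mRNA ceRNA pairs that share at least one miRNA across the two
negative networks. Using the pooled sample set maximises power and lets
condition-induced shifts contribute to the correlation, which is the
intended behaviour for a tumor-associated network; correlations restricted
to tumors can be obtained by subsetting the matrices first. Shared-miRNA
mediators are stored on each ceRNA edge, and a referential-integrity check
asserts every mediator has both negative-network edges.

At n = 563 the null standard deviation of r is ≈ 1/√562 ≈ 0.042, so an
independent (decoy) pair crosses |r| = 0.7 with essentially zero
probability — the filters' rejection path is exercised explicitly by decoy
catalog edges.

The miRNA–lncRNA candidate scanner is a deliberately minimal seed-match
rule: a hit is an exact occurrence of the reverse complement of the miRNA
seed (positions 2–8, a 7-mer) in the lncRNA, with no alignment score or
hybridisation energetics. Catalogs are the primary interface; the scanner
is a convenience for building them from sequence.

## MCODE

The three classic stages are implemented from scratch: k-core peeling for
core numbers (validated against an independent graph-library
implementation), vertex weight = k_max × density of the highest k-core of
the closed neighborhood, seeded breadth-first expansion including
neighbours with weight > seed_weight × (1 − vwp), then post-processing.
Defaults vwp = 0.2, haircut on, fluff off, min size 3. The haircut is
applied iteratively (the module's 2-core); density excludes self-loops;
ties in seed order and expansion are broken lexicographically by node id,
which makes the output fully deterministic. Modules are node-disjoint, and
each reported score is re-derivable as density × size from the member set.

One behaviour worth knowing: a single bridge between two cliques does
*not* split them — every clique vertex (bridge endpoints included) keeps
the full clique weight, so the expansion crosses the bridge and returns
one merged module. Separation requires low-weight vertices between dense
regions, which is exactly what sparse background provides in the
planted-clique benchmark. Note also that strictly bipartite
regulator→target networks are poor MCODE substrates: closed neighborhoods
there are stars with low density, so sparse bipartite runs can legitimately
return no modules.

## Topology

The scale-free check regresses log10 P(k) on log10 k by OLS over degrees
with nonzero frequency and reports slope and R². This simple estimator is
intentionally not a maximum-likelihood tail fit; on finite scale-free
graphs its R² is usually 0.8–0.9 but rare extreme-hub realizations scatter
the tail and can push R² below 0.7, so ensemble statements are made over
seeds.

Average path length is the mean shortest-path distance over *connected*
node pairs; disconnected pairs are excluded rather than imputed. The null
model rewires by double-edge swaps (a–b, c–d → a–d, c–b), rejecting
self-loops, parallel edges and, for typed networks, swaps that would break
the bipartite class structure; every node's degree is preserved exactly on
every draw. Each replica uses 10 × |E| attempted swaps — a standard mixing
heuristic. The empirical p is two-sided around the null mean with the
add-one correction, and the direction (real APL larger or smaller than the
null mean) is reported separately, since either direction can be the
interesting one depending on whether modularity lengthens paths or dense
blocks shorten them.

## Survival

The univariate Cox coefficient maximises the Breslow partial likelihood by
Newton–Raphson with step halving, convergence |Δr| < 1e−8, at most 100
iterations, on centred expression (centring leaves r unchanged and
improves conditioning). Breslow tie handling keeps the likelihood a smooth
1-D function that a grid search can verify directly; the fit is
cross-checked against an independent survival library on tie-free data.
Degenerate designs (fewer than 2 events, constant expression, monotone
likelihoods without a finite maximiser) raise errors rather than returning
boundary values.

RiskScore = Σᵢ rᵢ·Expᵢ, cutoff = cohort-mean score, with strict ">" into
the high-risk group (ties go low). Because each rᵢ is fit univariately,
coefficients are attenuated relative to the joint model when several
hazard genes act at once (omitted-covariate attenuation under
proportional hazards); the stratification chain detects planted
signatures regardless, which is the property that matters for the
screening use of the model. Kaplan–Meier estimation and the log-rank test
are delegated to `lifelines`; single-gene analyses split at the median
expression by default (mean available), and the survival endpoint is the
clinical table's (time, event) pair.

## Synthetic cohorts

The generator emulates a TCGA-style study: 505 tumor + 58 normal samples,
Gaussian log2-scale expression with per-feature baselines uniform in
[3, 9] and unit noise. Planted differential features shift the tumor mean
by ±effect (default benchmarks use 2.0). A planted triplet draws the
miRNA first and sets both targets to μ − β·(m − μ_m) + ε, giving
population correlations −β/√(β²+1) (miRNA–target) and β²/(β²+1)
(lncRNA–mRNA); β = 3 → −0.949 / +0.900, comfortably past the ±0.7 filters
at n = 563. DE shifts on the miRNA propagate to its targets with slope
−β, so coupled targets are automatically differential in the opposite
direction. Survival times are exponential with log-hazard linear in
designated genes' centred expression; censoring is an independent
exponential tuned so ≈30% of baseline patients are censored. Infiltration
scores are unit normals per cell type, with planted types mixed as
ρ·z(lncRNA) + √(1−ρ²)·noise over tumor samples.

What this shows — and does not. Passing benchmarks demonstrate that the
filter chain recovers the correlation structure it is designed for and
rejects independent decoys at realistic sample sizes. The generator is
deliberately Gaussian and i.i.d.: it does not emulate count noise,
batch effects, expression-dependent variance, correlated backgrounds or
real identifier spaces, so recovery rates here are upper bounds on
real-data behaviour, not estimates of it.

## Problem sizes in the test and acceptance runs

The test suite uses compact cohorts (≈160 samples, ≤40 features per
class) for unit checks, and the study-scale conditions (563 samples,
β = 3, effects 2.0) for recovery checks: 10 cohorts for triplet
recovery/decoy admission, 50 cohorts for the risk-chain power check,
n = 1000 for Cox coefficient recovery, 100 rewiring draws for the
degree-sequence invariant, 200 simulations for each calibration check.
The acceptance script runs one full-size cohort for the headline numbers
plus 5 cohorts for recovery rates and 1,000 rewired replicas for the
path-length null. These sizes were chosen to give stable statistics while
keeping a full run fast on a single CPU.

## Known limitations

- The pipeline treats the interaction catalogs as ground truth for the
  search space; catalog errors propagate directly.
- Correlation filtering over pooled tumor+normal samples conflates
  condition-driven and within-condition co-expression; a tumor-only mode
  is available by subsetting but is not the default.
- The seed-match scanner has no scoring model and should not be used as a
  target predictor beyond candidate generation.
- Univariate Cox weights ignore gene–gene correlation; the risk score is
  a screening device, not a calibrated prognostic model.
- MCODE results depend on vwp/haircut in ways that can only be validated
  against planted structure, not against a ground-truth modularity.
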