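# Methods

## Model

The analysis object is an undirected graphical model G = (V, E) over p
binary chronic-condition indicators. Estimation is nodewise: each node s is
regressed on the remaining nodes by L1-penalized logistic regression,

    minimize  −(1/n) Σᵢ [yᵢ ηᵢ − log(1 + e^{ηᵢ})] + λ Σⱼ |βⱼ|,
    ηᵢ = β₀ + Σⱼ βⱼ xᵢⱼ,

with an unpenalized intercept. At interaction order k = 3 the design
additionally contains all pairwise products of the other nodes, so
selected product terms describe diagnostic triads. An edge (s, t) exists
when the coefficient of t in s's model and/or of s in t's model is nonzero
(AND rule by default — conservative, both directions must agree; OR
available). The edge weight is the mean of the absolute contributing
coefficients, carrying the consensus sign when the two signs agree and
flagged `sign_defined = False` otherwise. For all-binary data this
pseudo-likelihood scheme estimates a pairwise binary Markov random field
(Ising model in 0/1 coding); edge weights are conditional log-odds
associations, i.e. association after controlling for all other conditions.

Predictors stay in their 0/1 coding, unstandardized. This keeps the
stationarity bound λ_max = maxⱼ |(1/n) Σᵢ xᵢⱼ(yᵢ − ȳ)| — the smallest
penalty with an all-zero solution — directly interpretable and matches the
generator's parameterization. Gaussian / multinomial node families are out
of scope: all conditions in the target data are binary.

## Lambda selection

Each node's path has `n_lambda = 50` values, log-spaced from λ_max down to
`lambda_min_ratio = 0.01` · λ_max, fitted with warm starts. Selection is by

    EBIC_γ = −2 ℓ̂ + df·ln n + 2 γ df·ln d,

with df = number of nonzero penalized coefficients and d = number of
candidate penalized terms; γ = 0 reduces to BIC and larger γ is more
conservative (selected df is provably non-increasing in γ on a fixed
path). The default γ = 0.25 balances sensitivity and precision; the
stability module refits at γ ∈ {0, 0.25, 0.5} and reports edge counts and
Jaccard overlaps. Ties in EBIC (and in CV deviance) go to the larger λ,
i.e. the sparser model, which makes runs bit-reproducible. K-fold
cross-validation (deterministic folds given a seed, mean out-of-fold
deviance) is available as an alternative selector.

## Solver

The penalized fits use an outer iteratively-reweighted quadratic
approximation with inner cyclic coordinate descent and soft-thresholding
(the standard penalized-GLM path algorithm), warm-started along the path.
Convergence is declared at a maximum coefficient change below 1e-7 per
outer iteration; non-convergence raises an error carrying the node and λ.
A relative KKT slack of 1e-10 snaps borderline coordinates to exactly
zero, so λ ≥ λ_max yields an exactly empty model. The test suite verifies
the attained objective against two independent routes: scipy L-BFGS-B on
the smooth split-variable reformulation (β = u − v, u, v ≥ 0) and
scikit-learn's saga L1 logistic, both to ~1e-6 in objective value.

## Predictability

Per node: in-sample accuracy of the selected model (predict 1 iff fitted
probability ≥ 0.5; ties classify as 1) against the intercept-only accuracy
max(p̂, 1 − p̂), combined as nAcc = (Acc − Acc₀)/(1 − Acc₀). nAcc is 0 for
an empty neighbourhood, 1 at perfection, negative when the selected model
misclassifies more than the majority rule, and undefined (reported
missing) when Acc₀ = 1. Accuracy is in-sample by design; a cross-validated
variant is deliberately out of scope.

## Centrality and communities

Graph measures use absolute edge weights (modularity is undefined for
negative weights; sign-ambiguous edges enter by magnitude). Degree is the
unweighted incident-edge count; strength the sum of |w|; shortest-path
measures use edge length 1/|w|; closeness is 1/(sum of distances to
reachable nodes) with unreachable pairs excluded; betweenness counts
weighted shortest paths with fractional credit for ties. Each measure is
also z-standardized across nodes (population SD; undefined when SD = 0).

Community detection is agglomerative greedy modularity maximization
(Clauset–Newman–Moore style): starting from singletons, repeatedly merge
the community pair with maximal ΔQ, breaking ties by the lexicographically
smallest pair of community representatives (smallest member index), and
return the first partition attaining the maximum recorded Q. Weighted
Newman modularity Q = Σᵢⱼ [Aᵢⱼ/2m − sᵢsⱼ/(2m)²] δ(cᵢ, cⱼ) is recomputed
independently for the returned partition and must match the greedy trace.
The naive O(p³) implementation is exact for the p ≤ 40 regime this package
targets and is cross-checked in tests against igraph's fast-greedy
clustering and an exhaustive-partition oracle on small graphs. Communities
are labelled MP1…MPm by decreasing size (ties: smallest member index).

## Bootstrap stability

B = 100 (default) resamples of n respondent rows with replacement;
respondents are the exchangeable unit in a cross-sectional survey. The
full nodewise estimator is refitted per replicate; each edge's sampling
distribution is summarized by the proportion of nonzero estimates, the
arithmetic mean of the weights (zeros included — the mean reflects the
point mass at zero; read it together with the nonzero proportion) and
empirical 5%/95% quantiles with type-7 linear interpolation. Replicates
that fail to fit are logged, excluded, and the effective B reported.

## Pattern assignment and profiling

The survey tells us which diseases a person has, not which pattern they
"belong to"; an explicit assignment rule is therefore needed. Each
respondent goes to the community containing the largest count of their
diagnosed conditions; ties go to the community whose matching conditions
have the larger summed prevalence, then to the lower MP index, and any
fired tie-break sets `tie_flag`. Membership is then modelled by a
baseline-category multinomial logit (maximum likelihood, statsmodels) with
age in years (linear) and social-class dummies against a configurable
reference class; the reference pattern defaults to MP1. Reported per term:
OR = exp(β), Wald 95% CI exp(β ± 1.96·SE), p-value and stars at
0.05/0.01/0.001. Pattern categories with fewer than 25 respondents are
dropped with a warning — near-empty categories make the shared likelihood
separable — and separated terms are flagged with unbounded CIs.

## Synthetic cohorts

The generator is a pairwise binary MRF P(x) ∝ exp(Σ αᵢxᵢ + Σ θᵢⱼxᵢxⱼ):
exactly the model class the k = 2 estimator targets, which makes edge
recovery a well-posed check. Couplings are block-structured; the default
within-block topology is a ring rather than a clique so the AND rule's
behaviour on sparse neighbourhoods is exercised. Sampling is single-site
systematic-scan Gibbs, one independent chain per respondent (rows are
exchangeable): random initialization from the independent-Bernoulli
approximation, 200 burn-in sweeps plus 5 thinning sweeps by default —
ample for p ≤ 40 at these coupling strengths, and verified against exact
2^p enumeration at small p (total-variation distance < 0.01 at 1e5
samples).

The survey-like preset plants 7 communities over the canonical 32-slot
condition list (cardiovascular-metabolic, musculoskeletal/pain,
respiratory/skin, digestive, excretory/sensory, mental health, and a
cancer/accidents residual) with marginal prevalences targeted to the
realistic 2–40% range via a mean-field intercept correction
α = logit(π) − ½ θπ. Covariates are drawn from survey-like marginals (age
≈ N(60.8, 17) clipped to [16, 95]; 40.7% male; bottom-heavy social-class
distribution) and act on block intercepts only — per decade of age above
60 and per class step above the midpoint — so the conditional-dependence
structure itself is covariate-free while profiling has a recoverable
gradient (cardiovascular, musculoskeletal and excretory blocks rise with
age; allergies fall; pain and complex blocks skew toward lower classes).
Slot 30 is the sex-specific pair: the sampled value is written to
`prostate_problems` for men and `menopausal_problems` for women, missing
for the other sex.

What the generator does not emulate: the survey's multi-stage sampling
design and weights, item-nonresponse patterns, regional heterogeneity, and
any longitudinal structure. Passing tests therefore demonstrate
correctness of the estimation machinery under a well-specified pairwise
model — not robustness to survey-design artefacts in real microdata.

## Problem sizes and determinism

Acceptance-level checks run at desk scale: structure recovery on p = 24,
n = 3000 over 10 seeds; bootstrap discrimination at B = 50 on a p = 10
fixture; profiling recovery over 50 replicates of n = 4000; generator
exactness at 1e5 retained samples. Every stochastic stage takes an
explicit seed; identical configuration yields byte-identical output
bundles, and each written table carries the run-manifest hash in a leading
comment line.

## Known limitations

- The AND/OR choice, edge-weight convention (mean absolute contributing
  coefficient with consensus sign) and the EBIC degrees-of-freedom
  definition are reasonable conventions, not identities; other toolchains
  may differ in borderline edges.
- In-sample predictability can be optimistic for weakly connected nodes;
  small negative nAcc values are possible and reported as-is.
- The individual→pattern assignment rule is a modelling decision; results
  of the profiling stage should be read conditional on it (tie frequency
  is reported via `tie_flag`).
- Greedy modularity maximization is a heuristic; it is exact on the
  disconnected-clique toys and recovers planted blocks in the tested
  regimes but has no global optimality guarantee.
- Categorical (>2 level) and continuous node families, survey weighting,
  time-varying models and graph drawing are out of scope.
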