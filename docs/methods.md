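# Methods

## The model

`netburden` treats gene-based rare-variant association as a two-stage
problem: (1) redistribute a sparse subject-level rare-variant signal over a
gene-interaction network so that each gene's score reflects the mutational
load of its functional neighbourhood, and (2) identify genes whose smoothed
scores separate cases from controls, with replication stability rather than
a single p-value as the evidence criterion.

### Burden encoding

Variants enter pre-annotated (gene, consequence class, reference-population
MAF, CADD phred). The default inclusion rule keeps exonic non-synonymous
variants with MAF < 1 % (strict) and CADD phred > 20 (strict — phred 20 is
the "top 1 % most deleterious" boundary and is excluded). An alternative
high-impact set restricts to stop-gain/stop-loss/frameshift, where
frameshift indels may be exempted from the CADD condition because indels
frequently lack CADD scores. The subject × gene matrix G⁰ encodes carrier
status (0/1) or counts; presence is counted once per variant regardless of
het/hom state, because sequencing-panel genotype quality rarely supports a
dosage interpretation of singleton variants.

Because deleteriousness annotation is phenotype-agnostic, a gene's rare
variation can be risk-increasing or protective; mixing the two blurs the
diffused signal. Orientation therefore calls a direction per gene from the
odds ratio of the carrier × case 2×2 table (Haldane–Anscombe +0.5 applied
when a zero cell occurs, for direction calling only) and, in `signed` mode,
multiplies protective columns by −1. OR exactly 1, all-carrier and
no-carrier genes are left unchanged and flagged `undetermined`. The
direction is estimated on phenotyped subjects only but applied to every
subject's column, since propagation is run on the full cohort while
selection uses the phenotyped subset; this asymmetry is deliberate and
visible in `orient_effects`' docstring.

### Propagation

The operator is the row-stochastic D·N with D = diag(1/strength); isolated
genes keep all-zero rows so indices stay aligned with the burden matrix.
The iteration G^{t+1} = α G^t (D·N) + (1 − α) G⁰ right-multiplies, i.e.
each subject's row vector diffuses along the operator's rows; the
multiplication side matters and is pinned by tests against hand-computed
star-graph examples. Convergence is declared when the Frobenius norm of the
iterate difference over the whole S × M matrix drops below `tol` (default
1e-6); the global norm is stricter than a per-row test. For α < 1 the map
is an affine contraction (the operator has spectral radius ≤ 1), so the
fixed point G* = (1 − α) G⁰ (I − α D·N)^{-1} exists; `closed_form_propagate`
computes it by a dense linear solve and is the package's internal oracle —
it is exact but O(M³), so it is intended for verification at small M, not
production runs. α = 1 is allowed but cannot converge to a burden-dependent
limit; the iteration stops at `max_iters` (default 1000) and either raises
or flags nonconvergence — an unconverged matrix is never returned silently.

Execution switches automatically between a sparse operator matmul (operator
density < 25 %) and a dense one; the two paths are tested to agree to
1e-10.

Quantile normalization of subject rows (each row mapped onto the mean of
all rows' order statistics, average ranks interpolated linearly so ties
share their target mean) is implemented for completeness but **off by
default**: on the simulation tiles it erases most of the case/control
difference in the hub score, which is expected — it forces every subject's
score distribution to be identical, so between-group differences survive
only in the ranks within rows.

### Binarization and null networks

Weighted networks can be reduced to an adjacency by keeping the top P %
(default 1 %) highest-weight edges. P is a percentage of *existing nonzero
edges*, not of all gene pairs — a percentage of pairs would retain far more
edges than the stated 1 % suggests. The retained count is ⌈P/100 · E⌉
(ceiling, so P > 0 never empties the graph) and ties at the cut weight are
broken by lexicographic gene-pair order for determinism. Degree-preserving
null networks are produced by double edge swaps (networkx), defaulting to
10× the edge count — a common mixing heuristic.

### Stability selection

The λ grid is log-spaced over [0.01·λ_max, λ_max] with 50 points, λ_max
computed from the standardized data as max_j |x_jᵀ(y − ȳ)|/n. Each of 100
resamples draws ⌊S/2⌋ subjects without replacement, stratified by class so
every fit sees both classes; complementary-pairs counting (both halves of
each split, probability granularity 1/200) is available but off by default.
Columns are standardized within each resample. Individual fits use
scikit-learn's liblinear solver with `intercept_scaling=10` so the
intercept is effectively unpenalized, wrapped in the sequential strong rule
(screen features by the gradient at the previous λ's solution, fit on the
screened subset, verify the Karush–Kuhn–Tucker conditions on the rest and
refit on violations) — a pure speed device that provably leaves the
solution unchanged and is tested against unscreened fits.

One design point was genuinely open: what happens at the nearly
unpenalized end of the grid. There the logistic model on a half-sample
(n/2 < M in the regimes of interest) saturates, supports grow into the
hundreds, and because half-samples overlap in half their subjects, genes
that are chance-correlated with the phenotype in the full sample re-enter
the model in most resamples — selection "probabilities" above 0.8 for pure
noise. Stability selection as implemented in the standard R tooling
controls this with a per-fit cap q on the number of variables allowed to
enter the path. `netburden` adopts that cap: `max_active='auto'` uses
q = ⌈√((2θ−1)·M)⌉, the Meinshausen–Bühlmann bound at an expected
false-selection count of one for threshold θ (q = 18 at θ = 0.8, M = 500).
Once a fit's support exceeds q, the path is frozen at the last support
within the cap. The cap can be disabled (`max_active=None`), reproducing
the uncontrolled behaviour.

Covariates are deliberately excluded from the sparse model; established
confounders enter afterwards through `evaluate.compare_models`.

### Simulation framework

The generator defines the study conditions under which the pipeline is
exercised: a two-ring star network (hub, n₁ = 10 first-ring genes attached
to the hub, n₂ = 50 second-ring genes attached round-robin to the first
ring, unit weights), cohorts of 200 cases and 200 controls, and carrier
status planted i.i.d. per gene and subject at frequency `f_case` or
`f_control` in the mutated tiers — first ring (scenario 1), second ring
(scenario 2) or both (scenario 3). The hub is never mutated, so any
case/control difference in its smoothed score is created by propagation
alone. 20 replicates per condition give stable tile estimates in well under
a minute. These sizes are the package's default desk-scale experiment;
they are deliberately small enough to iterate on.

The hub-score test is a two-sided Mann–Whitney rank-sum test (a t-test is
available behind a flag): the smoothed-score distributions the process
creates are mixtures and far from normal, and the rank test is also
invariant to the monotone rescaling that changing α mostly amounts to —
which is precisely why the tiles are insensitive to α. Bonferroni
multiplies by the number of cells in the current sweep.

What the generator does *not* emulate: linkage disequilibrium and haplotype
structure, relatedness, ancestry stratification, per-gene variant-count
heterogeneity, scale-free global topology beyond the star's ego view, and
measured covariates. Passing tests therefore show that the operator,
selection machinery and statistics behave as designed under a clean
generative model — not that the pipeline is robust to the confounding
structure of real cohorts.

### Downstream evaluation

`compare_models` fits nested logistic models (statsmodels) and reports the
1-df likelihood-ratio chi-squared p (Bonferroni-multiplied by the number of
genes tested, default the number of selected genes) and McFadden pseudo-R²
against the intercept-only model. Designs are reduced to a maximal
linearly independent column set by pivoted QR before fitting, so a score
collinear with a covariate yields LR = 0 exactly rather than a singular
Hessian; perfect separation is flagged and the p-value floored at the
machine minimum rather than reported as 0. Incomplete-case subjects are
dropped and logged.

The neighbour-overlap and enrichment randomization tests use the +1
permutation convention, p = (1 + #{null ≥ observed})/(n_draws + 1), so an
empirical p can never be 0 and its floor is 1/(n_draws+1). Enrichment is a
one-sided (greater) Fisher exact test — overrepresentation is the question
— with annotation sets intersected with the background first, expected
overlap |query|·|set|/|background|, and Benjamini–Hochberg adjustment
across sets at FDR 5 %.

## Numerical choices

- Convergence: global Frobenius norm, `tol = 1e-6`, `max_iters = 1000`,
  hard failure on nonconvergence.
- liblinear tolerance 1e-3 for path fits (supports, not coefficients, are
  consumed); `random_state=0` inside the solver for determinism; KKT
  violations tested at a 1e-4 relative slack.
- Duplicate edges on load: maximum weight kept (conservative for
  probabilistically weighted evidence), with a warning.
- Binarization ties: lexicographic gene-pair order.
- OR direction: +0.5 continuity correction only when a zero cell occurs.
- Empirical p-values: +1 convention throughout.
- Seeds: every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; derived seeds stay below 2³¹.

## Known limitations

- The closed-form oracle is dense and cubic in M; it is not usable at
  interactome scale (that is what the iteration is for).
- Orientation and selection assume a binary phenotype; continuous traits
  are not supported.
- The burden builder loops over variants in Python; it is comfortable at
  tens of thousands of variants but not engineered for biobank scale.
- Self-loops are supported in the container but the simulation and
  acceptance paths never exercise them beyond unit tests.
- Stability-selection probabilities depend on the standardization and cap
  conventions described above; numbers from other implementations are
  comparable only qualitatively.
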