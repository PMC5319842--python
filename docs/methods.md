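# Methods

## The design problem

A time-series profiling study must fix its sampling times before the
expensive genome-wide assays are run. `tpselect` assumes a *dense pilot*:
a small panel of G process-relevant genes (order 10²) measured at all n
candidate times t₁ < … < tₙ with R repeats per time point, e_gtr denoting
the r-th repeat of gene g at time t. Given a budget of k time points, the
task is to choose a subset C ⊂ {t₁,…,tₙ} with |C| = k, t₁, tₙ ∈ C, that
minimizes the squared error of spline reconstruction at the *unselected*
times:

    error(C) = Σ_g w_g Σ_r Σ_{t ∉ C} ( ê_g(t | C) − e_gtr )² ,

where ê_g(·|C) is a cubic smoothing spline fitted to gene g's repeat means
at the times in C, and w_g are optional per-gene weights (all 1 by
default). Candidate designs are compared by the error ratio
error(C_new)/error(C_old); below 1 means improvement. The normalized form
error(C)/#left-out-measurements is reported as the *average MSE*, the
quantity a practitioner compares against the repeat-noise floor.

Because the left-out times have really been measured in the pilot, the
objective is an honest cross-validation of the design itself, and every
proposed initialization or search variant can simply be scored on it and
the best kept.

## Spline model

The curve model is the classical natural cubic smoothing spline:
minimize Σᵢ (yᵢ − f(xᵢ))² + λ ∫ f″(u)² du. The minimizer is a natural
cubic spline with knots at the data points and fitted knot values
f̂ = (I + λK)⁻¹ y, with K = Q R⁻¹ Qᵀ the Green–Silverman roughness matrix.
Two consequences are load-bearing:

* **Closed-form LOOCV.** The leave-one-out residual is
  (yᵢ − f̂ᵢ)/(1 − hᵢᵢ) with hᵢᵢ the hat-matrix diagonal — exactly equal to
  an honest refit (asserted against independent refits in the tests).
  Endpoint folds are excluded, mirroring the rule that t₁ and tₙ are
  always profiled; ties prefer the smoother fit.
* **Vectorization.** For a fixed subset C and penalty λ, the hat matrix
  H(λ) and the prediction operator P(λ) = A·H(λ) onto the left-out times
  (A = natural-interpolation evaluation matrix) do not depend on the data,
  so one pair of small matrices scores *all* genes at once, and the
  smoothing penalty is re-selected per gene by LOOCV *for every candidate
  subset* at negligible cost. The loss over individual repeats decomposes
  as R_gt(ê − ē_gt)² + SS_within,gt with the within-cell term precomputed.

The public fitting API (`fit_spline`) parameterizes smoothness as an upper
bound `s` on the residual sum of squares — the constrained form of the
same problem — found by bisection on log λ (RSS is monotone in λ). `s = 0`
interpolates; `s` at or above the straight-line RSS returns the
least-squares line. With 2 points the fit is the connecting line; with 3
the natural boundary conditions keep the cubic well-posed, so budgets down
to k = 3 run.

The search engine's LOOCV grid is geometric with 15 values spanning
[10⁻³, 10²] × h̄³, where h̄ is the mean spacing of the candidate subset —
the penalty is invariant to the expression scale (both loss terms scale
with y²) but not to the time scale, hence the h̄³ factor. The public
`select_smoothing_loocv` uses the equivalent RSS-bound grid
[10⁻³, 10²] × (straight-line RSS of the profile).

## Search

* **Initializations** (all deterministic, ties to the earlier time):
  *equal partition* (grid points nearest an even division of the span;
  also the "uniform design" baseline), *absolute difference* (interior
  points ranked by Σ_g |Δ to left neighbor| + |Δ to right neighbor| of the
  repeat means; falls back to equal partition on flat data), and *max
  distance* (farthest-point traversal over the per-time mean-expression
  vectors). `--init all` runs greedy from every initialization and keeps
  the lowest-error result — the objective is computable, so initialization
  choice never needs to be guessed.
* **Greedy local search**: each iteration scores every
  (remove tₐ ∈ C∖{t₁,tₙ}, insert t_b ∉ C) pair and applies the pair with
  the lowest error ratio if < 1, else stops. The error trace is strictly
  decreasing and termination is certified by a final ratio ≥ 1. On the
  default fixture convergence takes well under 20 iterations. An optional
  *multi-swap* mode also scores the greedy composition of two successive
  swaps (a 2-out/2-in move) to escape ridges.
* **Simulated annealing**: uniform random single swaps, Metropolis
  acceptance exp(−Δerror/T), geometric cooling (default T₀ = 0.1 × initial
  error, rate 0.95, 50 proposals × 100 temperatures), best-ever set
  returned, fully seeded.
* **Exhaustive search** enumerates all C(n−2, k−2) subsets (capped at 10⁵)
  and serves as the oracle in tests; ties resolve to the lexicographically
  earliest subset.

Scored subsets are cached per dataset, so greedy, annealing and repeated
evaluations share work. Errors below 10⁻¹² are treated as exact zeros in
the ratio (noiseless data otherwise produces ratios of rounding noise).

## Cluster weighting

Co-expressed genes are redundant; unweighted loss lets a large cluster
dominate the design. Genes are clustered by k-means (10 restarts, seeded)
on per-gene z-scored repeat means (shape, not amplitude; optionally on
spline-resampled profiles evaluated at n uniform times — a deterministic
stand-in for random resampling of the fitted curve). The number of
clusters minimizes the x-means-form BIC of a hard-assignment spherical
Gaussian mixture: mixing proportions n_c/N, pooled variance
SS_within/(d(N−K)), parameter count K(d+1). The mixing-proportion term in
the classified likelihood is essential — without it the criterion
over-splits on any data, because a 2-means split always removes a finite
fraction of within-cluster SS while the ln N penalty stays bounded.
Weights w_g = 1/|cluster(g)| make each expression pattern contribute
equally (Σ_g w_g = K).

## Evaluation and baselines

`compare_methods` scores, per budget k: the selected design, the uniform
design, and n ≥ 19 random designs (endpoints plus a uniform draw of
interior points). The randomization p-value uses the add-one convention
(1 + #{random ≤ selected})/(1 + #trials), so it is never zero and 99
trials resolve p = 0.01. The repeat-noise floor reported alongside is the
bias-corrected per-measurement variance σ̂² = SS_within/(#measurements −
#cells); the raw within-cell statistic (which estimates σ²(R−1)/R) is also
exposed, measurement-weighted by default with a gene-averaged variant.
σ̂² — not σ²(R−1)/R — is the right floor for this loss: a predictor of a
*left-out* time point cannot see that cell's repeats, so its expected
squared error against a fresh repeat is at least σ².

`transfer_evaluation` selects points on a source dataset (the mRNA-style
pilot), scores them on a target dataset sharing the grid (miRNA-,
protein- or methylation-style), and compares with the target-native
selection and random designs on the target.

`evaluate_designs` scores *named historical designs* (sampling schedules
taken from prior studies, snapped to the pilot grid) under either spline
or piecewise-linear reconstruction, so a proposed design can be compared
against what the literature actually used; only the span a design covers
is scored, since prior studies often start later than the pilot.

`correlate_profiles` gives the Pearson r of two short profiles plus r over
all leave-one-out subsets, for concordance analyses between data types
measured at few shared times. `filter_methylation_sites` applies the
standard pre-filters to percentage-scale methylation profiles: temporal
range < 5 points removed, single-time-point spikes/dips exceeding both
neighbors by > 20 points removed, fewer than 3 non-zero time-means
removed.

## Synthetic study conditions

The generator emulates the dense developmental pilot regime: default grid
of 43 points (one prenatal point at −3.0 d, then every 0.5 d to day 14,
then daily to day 28), 126 genes in 8 co-expression clusters, 3 repeats,
Gaussian repeat noise σ = 0.33 (per-measurement variance ≈ 0.109 on the
log-expression scale). Cluster mean curves are a slow quadratic trend plus
2 logistic transitions with uniform-random centers, widths 0.3–2 d and
amplitudes 0.5–1.5 with random sign; genes add a small smooth deviation
(σ = 0.1) to their cluster curve. The paired generator reuses the source
cluster dynamics for the target — identical transition timing — with
transformed identities (identity / per-gene sign flip, the miRNA-style
default / global negation, methylation-style) and 1.5× repeat noise.

`corrupt_with_random_genes` replaces a fraction of genes with i.i.d.
Gaussian(0, repeat-noise sd) series, emulating a pilot panel in which only
the remainder is informative.

The change-point fixture is deliberately a sharp *transient* (Gaussian
pulse, sd = 1 grid step, shared event time on a 25-point unit grid, 40
genes, 3 repeats, σ = 0.2): for a monotone sigmoidal step the
reconstruction-optimal design brackets the transition from both shoulders
~2 steps away (verified against the exhaustive oracle), so "a selected
point within one grid step of the event" is only the right notion of
recovery for a localized event, which a design that skips it cannot
reconstruct.

What the generator does not emulate: count-level technical artifacts
(NanoString lane effects, saturation), heavy-tailed or heteroscedastic
repeat noise, missing-at-random dropouts beyond ragged repeats, and
between-gene correlation beyond shared cluster curves. Passing tests
therefore certify the combinatorial and numerical machinery under the
stated noise model, not robustness to platform-specific artifacts.

## Numerical choices and degenerate inputs

* Penalty-grid LOOCV ties → smoother fit; swap ties → earliest incoming
  time; exhaustive ties → lexicographically earliest subset; k-means
  empty-cluster fits retry up to 5 reseeded restarts.
* Hat-matrix LOOCV denominators are clipped at 10⁻¹²; with the grid's
  positive minimum penalty hᵢᵢ < 1 strictly.
* Constant genes cannot be variance/mean normalized and are excluded with
  a warning and a report; fully-missing (gene, time) cells are a
  validation error (the method assumes a dense pilot); individual missing
  repeats are simply dropped.
* Problem sizes in the automated property checks — 20 dataset seeds for
  the design comparisons, 100 small instances for the oracle study, 100
  runs for event recovery — were chosen to make Monte-Carlo margins wide
  relative to the asserted orderings while keeping a laptop-scale runtime.

## Known limitations

* The loss assumes homoscedastic repeat noise across genes and times;
  strongly heteroscedastic panels would need per-gene normalization first
  (`normalize_variance_mean`).
* Greedy search certifies only local optimality (single-swap, optionally
  depth-2); the exhaustive oracle is feasible to roughly C(n−2,k−2) ≤ 10⁵.
* Smoothing is selected per gene; a shared-smoothing option is not
  implemented beyond the fixed-penalty speed mode (`smoothing="fixed"`).
* No extrapolation: predictions are defined only within [t₁, tₙ], which
  the always-selected endpoints guarantee is sufficient.
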