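# Methods

This note records the statistical model behind `eaccd`, the defaults and
numerical conventions the implementation commits to, what the synthetic
benchmarks do and do not demonstrate, and known limitations.

## Model and assumptions

The pipeline treats each factor-level combination as a homogeneous
population and assumes **proportional hazards across combinations**: the
ratio of any two combinations' hazard functions is a constant. That
constant is an effect size independent of sample size, which is why the
folded hazard ratio `max(HR, 1/HR)` serves as the initial dissimilarity.
Censoring is assumed independent of the event process within combinations
(`event = 1` must mean the disease-specific death; deaths from other
causes are to be pre-coded as censored by the user).

The learned-dissimilarity step makes no additional statistical
assumptions; it is a consensus-clustering device that converts the
hazard-ratio scale into a rank-stable co-separation frequency. Its
off-diagonal values are structurally confined to `[1/n, (n-1)/n]` because
the ensemble includes `k = 1` (never separates) and `k = n` (always
separates); both ends are kept in the sum exactly as the ensemble is
defined, since excluding them would rescale every learned value.

## Estimators and numerical conventions

* **Kaplan-Meier**: product-limit over distinct observed event times;
  censoring times shrink risk sets without adding steps. An all-censored
  sample is a valid curve identically 1.
* **Two-sample Cox fit**: Newton-Raphson on the Breslow partial
  likelihood for a single binary covariate. Breslow was chosen as the
  simplest reproducible tie convention; with no tied event times it
  coincides with Efron, which is how the fit is cross-checked against
  lifelines in the tests. Convergence: gradient below `1e-9` per pooled
  event, at most 100 iterations with step-halving. A monotone likelihood
  (complete separation of event histories) is capped at `|log HR| = 20`
  and flagged `converged = False`; downstream code uses the capped value
  and logs a warning.
* **Harrell's C**: pair `(i, j)` comparable iff `t_i < t_j` and
  `event_i = 1`; tied observed times are never comparable; risk-score
  ties count 1/2. Computed in O(n log n) with a Fenwick tree over risk
  ranks; the tests pin it to exact equality with all-pairs enumeration.
* **PAM**: classical 2-phase algorithm — BUILD (first medoid minimises
  total dissimilarity, each next medoid maximises cost reduction), then
  steepest-descent SWAP (best single medoid/non-medoid exchange until no
  improvement). Every tie breaks toward the lowest index, so partitions,
  learned dissimilarities and everything downstream are pure functions of
  the input matrix. Note that PAM is a *local* search: on unstructured
  random matrices the returned cost can exceed the exhaustive-search
  optimum in a few percent of runs (the canonical R `cluster::pam`
  implementation shows the same rate on identical inputs). On
  well-separated block structure — the regime the pipeline relies on —
  it recovers the optimum, which the tests assert.
* **Complete linkage**: naive O(n^3) agglomeration, adequate for the
  combination counts this method targets (tens to a few hundred); ties in
  the minimum inter-cluster distance break toward the smallest (older,
  then younger) node id. Heights are non-decreasing by monotonicity of
  complete linkage. Cutting is by merge count (exactly `k` groups) rather
  than by a height threshold, because heights can tie and the C-index
  curve is indexed by the number of groups; `cut_at_height` is exposed as
  a secondary entry point.
* **Group risk scores**: each group is scored by the negative of its
  pooled KM restricted mean survival time over `[0, horizon]` (default
  horizon: the largest observed event time). Restricted mean is monotone
  in stochastic ordering of survival and robust to censoring. Scores are
  reduced to dense ranks so that groups tied on both the restricted mean
  and the 5-year survival tie-breaker (e.g. identical member sets) remain
  risk-tied for the concordance index; the final group numbering breaks
  any residual order ties by smallest combination label. The 5-year
  tie-break point (t = 60) assumes months; it only matters for exact
  restricted-mean ties.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_cases` | 100 | minimum patients per retained combination; ensures enough cases (and deaths) for stable pairwise Cox fits. Combinations without any event are additionally dropped, since their hazard ratios are unidentifiable. |
| `horizon` | largest observed event time | upper limit of the restricted-mean integral (same time units as the data) |
| `tolerance` | 0 | C-index plateau tolerance for selecting `n*`; 0 reproduces the strict "smallest k attaining the maximum" rule |
| `force_k` | none | overrides selection, for externally motivated group counts (e.g. matching an existing staging system's size) |

## Synthetic benchmarks: what they emulate, and what they do not

The generator draws exponential event times per combination (Weibull with
a shared shape as a PH-preserving stress option), so the proportional-
hazards assumption holds *exactly* and hazard-ratio recovery is a clean
oracle. Censoring is an independent exponential time truncated by an
administrative cutoff, emulating a fixed follow-up window.

The standard recovery benchmark plants 12 combinations in 3 equal-hazard
tiers (0.02 / 0.05 / 0.10 events per month, 500 patients each, censoring
rate 0.01/month under a 132-month cutoff, ~20% censored overall — a
follow-up window and censoring level typical of registry extracts). The
planted partition is the ground truth against which the selected cut is
scored. For the synthetic studies the plateau tolerance is set to 0.01,
about three Monte-Carlo standard errors of the C-index at the benchmark
size (6000 patients): splitting an equal-hazard tier perturbs C only by
sampling noise, and the tolerance keeps `n*` at the planted tier count
instead of chasing that noise. The same reasoning bounds the observed gap
between C at the cut and C at full resolution (`k = 12`) by 0.015.

Real registry data differ in ways the generator deliberately does not
model: non-proportional (crossing) hazards, covariate-dependent
censoring, calendar-time trends, unequal combination sizes, and
misclassified factor levels. Passing the planted-structure tests
therefore validates the machinery under the method's own assumptions, not
robustness to their violation.

## Design choices where the design was open

* The per-group predictor feeding the C-index is not pinned down by the
  verbal definition of the method; negative restricted mean survival was
  chosen (see above) over alternatives such as median survival (undefined
  when the curve stays above 1/2) or 5-year survival alone (discards the
  rest of the curve).
* `n*` selection exposes both the strict rule (`tolerance = 0`) and a
  plateau tolerance, plus a forced `k`, because published groupings are
  sometimes chosen partly for comparability with existing systems rather
  than by the strict maximum.
* The diagonal of the initial matrix is 0 even though a self hazard
  ratio is 1: PAM and linkage require zero self-dissimilarity; the
  off-diagonal stays on the >= 1 hazard-ratio scale.
* The C-index is computed on patient-level data, never on combination
  summaries.
* Analysis commands are seed-free and fully deterministic; all
  randomness is confined to the simulator. Pairwise Cox fits are
  embarrassingly parallel, but the single-threaded loop is already fast
  at realistic combination counts, and keeping it serial guarantees
  bit-identical output trivially.

## Limitations

* Single binary covariate Cox fits only — no multivariable adjustment,
  time-varying covariates, or competing-risks estimators.
* C-index and KM curves are point estimates; no confidence intervals.
* Complete linkage only (no average/Ward variants), and exact PAM rather
  than approximations, so very large combination counts (thousands) would
  need algorithmic upgrades.
* Factor levels are opaque labels: clinical recoding (grade collapsing,
  age banding) must happen upstream.
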