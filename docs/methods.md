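# Methods

This note documents the statistical model behind phytocart, the choices made
where the design was genuinely open, and what the shipped synthetic scenario
does and does not establish about real field data.

## Tree growth

Trees are grown on ln-transformed responses by exhaustive variance-reduction
search.  Node error is the population-form sample variance (divisor N, not
N−1); the split score is the parent variance minus the sample-size-weighted
child variances, equivalently the reduction in the node's sum of squared
errors divided by the node size.  Threshold candidates are midpoints between
consecutive distinct sorted values of each predictor: printed split points in
field CART studies (e.g. 1.795 mg/L for DO, 3.720 mg/L for TN) are of exactly
this form, and midpoints make predictions stable to measurement jitter.
Routing is `x < t` → left, `x ≥ t` → right, matching the convention in which
the high branch owns the threshold value.

Determinism: splitting involves no randomness.  Ties in the decrease are
broken toward the earlier predictor in `variable_order` (default: the
conventional column order WT, DO, EC, pH, ORP, Tur, TN, TP) and then toward
the smaller threshold.  Equal decreases between distinct candidates are a
measure-zero event for continuous data but occur for duplicated columns and
symmetric toy responses; the tie-break makes those cases reproducible too.

Stopping rules (all tunable via `FitSettings`): `min_leaf=2`, `min_split=4`,
`min_decrease=0`, unlimited depth.  The defaults deliberately overgrow —
model selection belongs to pruning, not to stopping heuristics.  Rows with a
missing value in any declared predictor or the response are dropped before
fitting (logged); there are no surrogate splits, so prediction requires
complete rows for the variables a tree actually splits on.

## Pruning

The resubstitution error R(T) is the weighted leaf variance
Σ_leaves (n_l/N) · var_l = Σ_leaves sse_l / N.  It is additive over leaves and
equals the training-set variance for the root-only tree, which is what makes
the critical complexity parameter α(n) = (R(n) − R(T_n)) / (|leaves| − 1)
well defined for a regression tree.  Weakest-link pruning collapses the
minimal-α internal node(s) — ties collapse together, keeping the path nested
and the recorded α sequence strictly increasing — and provably yields, at
every α, the subtree minimizing R(T) + α·|leaves(T)| among all rooted
subtrees (the test suite verifies this against exhaustive enumeration, and
the α sequence against an independent implementation).

Final-subtree selection offers two policies because published analyses often
report only the final leaf count, not the selection rule:

* `LeafCountPolicy(k)` — the path entry with the most leaves ≤ k;
* `CVPolicy(folds, rule, seed)` — k-fold cross-validation over the α
  sequence, evaluated at geometric midpoints of consecutive α values.  The
  per-fold grow+prune is refit from scratch.  `rule="min"` takes the
  CV-minimal α (ties resolved toward the sparser tree); `rule="one_se"`
  takes the sparsest subtree within one standard error of the minimum, with
  the SE estimated from per-fold mean losses (sd/√K).  The 1-SE rule is the
  better structure-recovery rule; the min rule the better predictor.

## Importance and split signs

Per-node decreases are weighted by n_node/N_root before summation, so
contributions are commensurable across depths and satisfy the conservation
identity Σ qᵢ = root variance − weighted leaf variance.  Two normalizations
are reported deliberately: `pc_share` (share of summed contributions, summing
to 1) and `pc_root` (share of *total* response variance, summing to the
tree's explained variance).  Field papers commonly report the latter — a set
of per-variable percentages plus an "all variables explained X%" total — and
the two coincide only for a tree explaining all variance.

A split is signed positive when the ≥-side child has the larger mean
response.  Signed counts per variable expose non-monotone effects (a variable
with both + and − splits acts positively in some environmental combinations
and negatively in others); the sign definition follows the narrative
convention that "a positive influence" means higher response above the
threshold.

## Holdout validation

Each run draws a uniformly random 2/3–1/3 train/test partition (run-indexed
substream of the seed, so the 200-run protocol is exactly reproducible and
runs are independent), refits grow+prune with the same policy as the headline
fit, and scores ER = (1/n) Σ |y − y_pred| / y on the model (ln) scale.  The
absolute value is a deliberate choice: a signed mean lets over- and
under-predictions cancel and would not measure precision (the signed variant
is kept as an option).  Relative error on the ln scale is scale-free and
numerically small because ln-responses of realistic magnitudes (≈ 3–15) sit
far from zero; the raw-scale option gives larger, also meaningful, values.

## Synthetic scenario

The generator emulates three features of the motivating field system:

1. **Per-month marginals.**  Eight bimonthly open-water campaigns × eight
   variables, each summarized as mean ± SD (min, max).  Each cell is drawn
   from a four-parameter (scaled) Beta on [min, max] whose shape parameters
   are moment-matched in closed form to the published mean and SD.  A normal
   truncated to the printed range cannot represent several turbidity months —
   their SD exceeds the truncated-normal supremum of range/√12 (e.g. SD 258
   on a range of 592) — while the Beta family covers every published cell,
   respects the hard bounds, and introduces no boundary atoms.
2. **Dependence.**  A Gaussian copula with a single global latent correlation
   matrix; month effects enter through the marginal means.  Because published
   correlation coefficients are *pooled* over campaigns, and month-mean
   shifts alone induce rank correlation, the within-month latent correlation
   is calibrated (deterministic fixed-seed bisection against the mixture
   model, with a PSD-projection fixed-point loop) so the pooled Spearman of a
   generated table matches the configured target.  Unpublished pairs default
   to a target of 0 and stay within-month independent — an assumption, since
   only significant coefficients were published.  Not every target set is
   jointly feasible: the EC–Tur target (0.51) would need a within-month
   latent correlation incompatible (under positive semidefiniteness) with the
   EC–TN and EC–TP targets, and saturates near 0.40; the generator logs this.
3. **Responses.**  Known 4-leaf piecewise-constant surfaces on the ln scale —
   abundance splitting on TN (3.720 mg/L), WT (10.25 °C) and TP (0.90 mg/L),
   richness on DO (1.795 mg/L), TP (1.629 mg/L) and ORP (176.65 mV) — plus
   Gaussian noise (defaults: SD 0.2 for ln-abundance, 0.06 for ln-richness,
   set so total ln-scale variance and explained fraction are of the magnitude
   a field campaign of this kind reports).  Leaf means are fixtures at
   realistic ln-scale magnitudes, not estimates of any real surface.
   Richness is back-transformed and rounded to a positive integer; abundance
   exponentiated.

What passing tests on this scenario show: the full pipeline — growth,
pruning, importance, validation — correctly recovers known structure from
data with realistic marginals, dependence and noise.  What they do not show:
anything about unmodeled features of real field data (serial and spatial
autocorrelation among sites, non-tree response surfaces, measurement error in
predictors, missingness mechanisms), none of which the generator emulates.

## Numerical choices and problem sizes

* Split scan: prefix-sum formulation, O(p · n log n) per node; decreases are
  clipped at 0 against catastrophic cancellation; a zero-decrease "split" is
  treated as no split.
* Pruning: ancestor-incremental recomputation after each collapse; α ties
  within 1e-12 (relative) collapse together.
* CV error: per-node test statistics are accumulated in one routing pass per
  fold, so evaluating the whole α sequence costs little more than one
  prediction pass.
* Copula calibration: bisection tolerance 2e-3 on the latent correlation,
  2000 Monte-Carlo draws per month on a fixed internal stream (Monte-Carlo
  error ≈ 0.008 on a pooled Spearman), cached per scenario content.
* Default experiment sizes — 216-sample headline analyses, 200-run holdout,
  20-replicate recovery at n = 2000, marginal fidelity at n = 5000/month —
  are the package's standard test protocol; all complete in minutes on one
  core.

## Known limitations

* Threshold recovery is resolution-limited in a specific, quantifiable way:
  even with the right variable selected, estimation error in an ancestor's
  threshold leaks a few misassigned observations into child nodes, so child
  thresholds typically land within a few observation spacings of the truth
  (relative error ≤ ~0.6% at n = 2000, noise SD 0.05) rather than inside the
  exact bracketing gap; the bracketing-gap property holds only in the
  noiseless limit.
* The CV 1-SE rule still admits an occasional extra split in ≈10% of
  recovery replicates — a duplicate on a true variable or a proxy split on a
  correlated variable (EC, Tur) that genuinely separates observations
  misassigned by an ancestor's threshold error; all generating splits are
  nevertheless recovered in every replicate.
* No surrogate splits or categorical predictors; missing predictor values
  drop rows at fit time and fail rows at predict time.
* KS normality checks use estimated group parameters; nominal p-values are
  conservative (Lilliefors caveat).
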