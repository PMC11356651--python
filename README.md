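# phytocart

Regression-tree analysis of how fluctuating environmental conditions drive
phytoplankton **species richness** and **abundance** in rivers, built for
community ecologists and water-quality analysts who want an interpretable,
nonparametric alternative to linear ordination methods.  The feature table is
one row per (site, month) sample with eight environmental predictors — water
temperature (WT, °C), dissolved oxygen (DO, mg/L), electrical conductivity
(EC, µS/cm), pH, oxidation–reduction potential (ORP, mV), turbidity (Tur,
NTU), total nitrogen (TN, mg/L) and total phosphorus (TP, mg/L) — and the two
ln-transformed community responses.

## The method

**Growth (CART, regression mode).**  A binary tree is grown by recursive
partitioning.  The error of a node *D* holding responses *y₁…y_N* is the
sample variance

    E(D) = (1/N) Σᵢ (yᵢ − ȳ)²

and each split maximizes the variance decrease

    E = E(D) − (N₁/N) E(D₁) − (N₂/N) E(D₂),

searched exhaustively over every predictor and every midpoint between
consecutive distinct observed values.  Rows with *x* < *t* go left, *x* ≥ *t*
right; ties between candidates are broken deterministically (earlier
predictor, then smaller threshold), so identical input gives identical trees.

**Cost-complexity (weakest-link) pruning.**  With R(T) the leaf-additive
resubstitution error, each internal node *n* has a critical complexity
parameter

    α(n) = (R(n) − R(T_n)) / (|leaves(T_n)| − 1).

Repeatedly collapsing the minimal-α node yields a nested sequence of optimal
subtrees from the full tree down to the root; the final subtree is chosen
either by an explicit leaf budget or by k-fold cross-validation over the α
sequence (minimum-error or one-standard-error rule).

**Variable contributions and split signs.**  A variable's contribution *qᵢ*
is its summed, sample-size-weighted variance decrease over all its splits,
reported both as a share of all contributions, PCᵢ = qᵢ / Σⱼ qⱼ, and as a
fraction of the total response variance (these sum to the tree's explained
variance).  Each split is signed **+** when the high side of the threshold has
the larger mean response and **−** otherwise, exposing non-monotone
(e.g. unimodal) effects.

**Validation.**  Repeated random 2/3–1/3 train/test partitions (default 200),
the tree refit on each training set, precision summarized as the mean relative
prediction error ER = (1/n) Σⱼ |yⱼ − y_pred| / yⱼ on the model scale.

**Synthetic data.**  Because the motivating field data are not publicly
deposited, a calibrated generator ships with the package: per-month marginals
are four-parameter Beta distributions on the observed [min, max],
moment-matched to the published mean ± SD of each campaign month; variables
are coupled through a Gaussian copula calibrated so the *pooled* Spearman
correlations match the published coefficients; responses come from known
4-leaf ground-truth trees on the ln scale plus Gaussian noise.  Every stage of
the pipeline is therefore testable end to end, including parameter recovery.

## Worked example

```python
import phytocart as pc

cfg = pc.default_scenario(seed=1)          # 8 months x 27 sites = 216 samples
table = pc.generate_dataset(cfg)
ln_tab = pc.ln_transform(table, "abundance")

tree = pc.grow_tree(ln_tab, "abundance")   # deep growth: 91 leaves
path = pc.prune_path(tree)
final = pc.select_subtree(path, pc.CVPolicy(folds=10, rule="min", seed=1),
                          table=ln_tab, response="abundance")
report = pc.variable_contributions(final)
print(report.to_frame().round(4).to_string(index=False))
val = pc.holdout_validate(ln_tab, "abundance",
                          prune_policy=pc.LeafCountPolicy(final.n_leaves),
                          n_runs=200, seed=1)
print(val.summary())
```

prints

```
variable      q  pc_share  pc_root  n_positive_splits  n_negative_splits
      TN 0.1194    0.7385   0.6046                  1                  0
      WT 0.0280    0.1729   0.1416                  1                  0
      TP 0.0143    0.0886   0.0725                  1                  0
ER = 1.11% ± 0.10% (mean ± SD over 200 runs, ln scale)
```

Cross-validated pruning cuts the 91-leaf tree to the 4-leaf generating
structure; TN carries 60% of total ln-abundance variance (74% of the summed
contributions), WT and TP the rest, all with positive high-side effects, and
the tree explains 81.9% of response variance in total.  The repeated-holdout
error of 1.11% ± 0.10% says refit trees predict held-out ln-abundance to
about one percent relative error under these noise conditions.

The same pipeline runs from the shell:

```bash
phytocart simulate --seed 1 --out table.csv
phytocart fit table.csv --response abundance --out tree.json
phytocart prune tree.json --policy cv --table table.csv --out final.json
phytocart importance final.json --out importance.csv
phytocart validate table.csv --response abundance --leaves 4 --out runs.csv
phytocart run pipeline.yaml     # the whole chain from one config
```

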