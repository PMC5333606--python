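# Methods

## The model

Each subject is a vector of `n_f` biomarker values (numeric labs and 0/1
history flags). A reference population — here the *survivors*, treated as
the "healthy" group — defines, for every unordered feature pair `{k, l}`
(index order `k < l`), an ordinary least-squares baseline

    f_l = α_{k,l} + β_{k,l} · f_k + ε_{k,l},

with `σ_{k,l}` the sample standard deviation (ddof = 1) of the residual
vector. A subject `h` is then mapped to a fully weighted graph over the
features — a *parenclitic* (deviation) network — with edge weights

    w_{k,l} = ( f_{h,l} − (α_{k,l} + β_{k,l} · f_{h,k}) ) / σ_{k,l},

the Z-score of the subject's distance from the reference relation. For a
subject drawn from the reference population, `w` is approximately standard
normal on every pair; deviant physiology shows up as large `|w|`.

Networks are binarized by keeping links with `|w|` **strictly** greater
than a threshold (default 0.5; links with `|w| ≤ 0.5` are discarded). For a
fresh reference subject and an exactly linear-Gaussian cohort the expected
binarized link density is the normal two-tail mass `2·(1 − Φ(0.5)) ≈ 0.617`
— a useful analytic anchor that the test suite checks.

Two scalars summarize each binarized network for classification:

* **Link density** — links divided by `n_f(n_f−1)/2` possible links.
* **Information Content (IC)** — bits of information lost while greedily
  merging the most similar node pairs until one node remains. A candidate
  pair `(u, v)` costs `m · H₂(d/m)`, where `m` is the number of other
  remaining nodes, `d` of them are connected to exactly one of `u, v`, and
  `H₂` is the binary entropy; the minimum-cost pair is merged into a node
  carrying the union of both link sets, and the costs accumulate.

### IC design choices

* **Tie-breaking and invariance.** Greedy ties are broken by the lowest
  index pair, but raw input indices make the result depend on how nodes
  happen to be labelled (two labelings of one 12-node graph differed by
  over 8 bits in development). Indices are therefore taken from a
  *canonical labeling* computed before the merge loop: iterated colour
  refinement (1-WL) when it individualizes every node — the typical case
  for the dense irregular graphs this pipeline produces — with BLISS
  canonical labeling (igraph) as the fallback for symmetric graphs. IC is
  then a true graph invariant: isomorphic graphs score equal, exactly.
* **Self-pair exclusion.** The `u–v` edge itself is excluded from the
  disagreement count; it is consumed by the merge.
* **Conventions.** Graphs with fewer than 3 nodes score 0 (no third node's
  pattern to encode). Complete graphs and stars score 0 (all patterns
  within a merge class agree).
* **Direction on standard ensembles.** On Erdős–Rényi graphs versus
  equal-density 3-block modular graphs (n = 30, density 0.3), the *random*
  graphs score **higher**: unstructured connection patterns disagree
  almost everywhere, so every merge is expensive, while modular structure
  offers cheap merges inside blocks. Folklore sometimes states the
  opposite ("high IC = non-trivial topology"); with this merge-cost kernel
  the compression intuition wins, and it is the separation, not the sign,
  that carries discriminative information. The test suite records the
  observed direction.
* **Complexity.** The production path maintains pairwise disagreement
  counts incrementally (O(n³) per graph, numba-compiled, ~1 ms at n = 92);
  tests compare it against an independent per-step recomputation.

## Classification protocol

Two scenarios are compared with a linear SVM (L2-regularized squared
hinge, liblinear, C = 1, no tuning) under one shared stratified 10-fold
partition: **raw** (biomarker columns only) and **enhanced** (the same
columns plus link density and IC). Features are standardized with
training-fold statistics. Greedy forward selection adds the candidate with
the best cross-validated accuracy, stopping when the gain drops below
0.005 or at 5 features; selection runs on the same partition used for
reporting (non-nested — the optimistic bias this shares with compact
clinical-model building is noted in the README). The score is accuracy;
classes are balanced by construction, so error = 1 − accuracy.

**Leakage control.** Whenever network features are used, each fold refits
the pairwise baseline on its *training survivors only* and derives both
training and test subjects' network features from that fold-local
baseline. No test subject touches baseline fitting, standardization
statistics, or SVM training; a dedicated test replaces a fold's test
subjects with fresh data and asserts the fitted baseline and scaler
statistics are bit-identical.

## The synthetic cohort generator

The generator emulates the statistical structure the method assumes about
a trial biomarker table: 80 numeric + 12 binary features, balanced
survivor/non-survivor labels.

* **Reference structure.** A seeded sparse random set of linear relations
  (default 70) over the numeric features: each response feature appears
  once as a response, every feature joins at most 3 relations, and the
  predictor always has the lower index (so the generation direction
  coincides with the fitted regression direction). Noise is
  *variance-stationary*: `noise_sd = sqrt(1 − slope²)` with |slope| ∈
  [0.5, 0.9], so every feature has unit variance regardless of its depth
  in the dependency graph — pairwise R² of about 0.25–0.8, the range one
  sees among related clinical labs. Intercepts are uniform in [−1, 1];
  root features are standard normal; binaries are Bernoulli (default rate
  0.3, class-specific rates configurable).
* **Case deviations.** On each perturbed pair the response is shifted by
  `delta · noise_sd` with a per-subject random sign. The random sign keeps
  the response's marginal mean unchanged — the planted signal lives in the
  pairwise relation and is invisible to a linear classifier on raw
  features — while the expected absolute Z-score on the perturbed pair is
  the folded-normal mean `E|N(±δ, 1)| ≈ δ` (for δ ≥ 2). Alternative
  mechanisms (slope change, noise inflation) are exposed as
  `deviation_mode` options but carry no analytic guarantee.
* **Placement of perturbations.** In the default benchmark the perturbed
  10% of relations are chosen deterministically as those with the
  highest-index responses. Under single-direction regression an unrelated
  pair's weight is essentially the response feature's own z-score, so a
  deviation's visibility scales with how many fitted pairs have that
  feature on the response side; deterministic high-coverage placement
  plants the signal where the network stage can in principle see it,
  instead of letting benchmark difficulty vary by topology lottery.
* **Marginal effect.** One relation-free numeric feature gets a case mean
  shift of 1.2 control-sd units, giving a single-feature Bayes accuracy of
  Φ(0.6) ≈ 0.73 — the scale of a strong clinical prognostic biomarker
  (LDH plays this role in prostate-cancer survival data).
* **Default benchmark.** 2000 subjects (1000/1000), 92 features, 70
  relations, 7 perturbed pairs at δ = 2, one marginal feature. On these
  conditions the class separation of link density is d ≈ 0.6 (and IC
  d ≈ −0.6; cases, whose planted deviations form structured hubs, score
  *lower* IC per the direction note above), which yields a raw accuracy
  near 0.73 and a reliably higher enhanced accuracy.

### What the generator does *not* emulate

Real trial tables have skewed lab distributions, missingness, censoring,
batch effects between trials, and nonlinear physiology. Passing tests on
this generator show the pipeline's machinery is correct and that the
protocol detects relational signal without leaking it — they do not show
that real cohorts contain such signal at any particular strength.

## Numerical choices

* Pairs with predictor variance < 1e-12 or residual sd < 1e-8 are flagged
  degenerate: weight 0, never a link (avoids division by zero for
  collinear or constant features).
* Missing values silence only the pairs they touch (weight 0, logged).
* Binary features enter regressions as 0/1 numerics.
* Binarization is strict (`|w| > t` keeps the link).
* Regression direction is higher-index-on-lower-index, one regression per
  unordered pair — the minimal reading; both-direction symmetrization was
  considered and rejected to keep one weight per pair and the 0.617
  density anchor exact.
* Greedy selection always accepts its first feature; ties go to candidate
  order.

## Problem sizes used in tests and the acceptance script

Oracle equivalence runs on 50 micro-cohorts (≤ 6 subjects, ≤ 4 features);
the density anchor on 5000 training + 500 fresh controls; IC oracle
agreement on all 208 non-isomorphic graphs with ≤ 6 nodes plus 100
relabelings; ensemble separation on 200 + 200 30-node graphs; null safety
and the headline comparison on full 2000 × 92 cohorts. The test suite
repeats the headline comparison on 20 seeds; the acceptance script uses 5
repetitions, a size chosen to keep a full from-scratch rerun convenient
while still averaging over cohort draws.

## Known limitations

* IC's greedy merge is a heuristic compression; it is not the optimal
  code length of the graph, and other cost kernels would order ensembles
  differently.
* Non-nested feature selection modestly inflates both scenarios' absolute
  scores; the raw-vs-enhanced *comparison* shares the bias.
* The WL/BLISS canonicalization makes IC exactly invariant but means IC
  values are not comparable with implementations that break ties by input
  order.
* With a single fitted direction per pair, deviations planted on
  low-coverage response features are nearly invisible to link density; the
  `symmetrize`-style alternative (max |w| of both directions) was left out
  of scope.

## Null behaviour of the reported scores

On a zero-effect cohort any *fixed* feature set cross-validates at 0.50,
but the reported scenario scores sit a few points higher (typically
0.52–0.56): the greedy selector reports the maximum of ~92 noisy fold-mean
estimates and each accepted step can add another increment of noise. This
is the familiar optimism of non-nested selection, shared equally by both
scenarios, and is why the raw-vs-enhanced *difference* — not the absolute
level — is the meaningful readout. The acceptance script reports a
selection-free fixed-feature null alongside the scenario nulls to make the
decomposition visible.
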