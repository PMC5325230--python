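# Methods

## Model and assumptions

`triway` operates on a complete information table: every object has exactly
one value for every attribute and for the decision column (missing cells
are rejected at load).  All inference is at the level of equivalence
classes — objects sharing an attribute signature are indistinguishable —
so continuous attributes must be discretized before they can contribute to
a partition.  The concept is binary (one decision label versus the rest);
multi-label problems are handled one-vs-rest, each label an independent
concept.

Block conditional probabilities `P(C|[x])` are computed as exact rationals
(`fractions.Fraction`).  Threshold comparisons use the defining
inequalities `≥ α` / `≤ β`, so ties at a threshold go to the decisive
region; when float thresholds are unavoidable (learned values, dense
grids) comparisons carry a 1e-12 slack.  `β = α` is forbidden at
construction, since the positive and negative regions would overlap there.

## Discretization

The partition-on-equality requirement gives no canonical treatment of
counts and weights, so binning is an explicit, configurable preprocessing
step: equal-frequency (default, 5 bins) or equal-width, fitted on training
data only.  Equal-frequency is the default because count-valued biological
features are heavily skewed and equal-width binning would leave most bins
empty.  Fitted cut points are stored in the table metadata and re-applied
to held-out objects; values outside the fitted range clamp into the
extreme bins.  A constant column yields a single bin without error.

## ITRS

Total uncertainty is `Δ(α,β) = Σ_R P(R)·δ_R` over the three regions, with
`δ_R` the Shannon entropy (base 2, bits) or Gini coefficient of
`P(C|R)`; `0·log 0 = 0`, and an empty region is assigned `δ_R = 0` (its
weighted contribution is zero regardless, and this keeps Δ continuous in
region size).  Because regions change only when a threshold crosses a
block probability, Δ is piecewise constant and the global optimum is
attained on the finite grid of distinct block probabilities augmented with
{0, 1}.  We therefore search that candidate grid exhaustively — exact and
deterministic at this scale — rather than by gradient descent; a uniform
0.01-step grid is retained as an independent cross-check (`search=
"dense_grid"`).  Note the candidate grid can be strictly better than the
dense grid when two block probabilities fall inside one 0.01 cell.  Ties
among minimizers break toward the largest α, then the smallest β, i.e.
the most conservative pair, closest to the Pawlak model.  The Δ surface is
evaluated vectorized over all candidate pairs (numpy), which keeps the
oracle comparisons and cross-validation loops fast.

## GTRS

The game has two players with finite strategy sets: {stay} ∪ {lower α by
s} for player 1 and {stay} ∪ {raise β by s} for player 2, with step sizes
{0.05, 0.10} by default.  Profiles whose resulting thresholds violate
`0 ≤ β < α ≤ 1` are infeasible and score −∞ for both players.  Payoffs are
evaluated at the profile-modified thresholds:

* uncertainty variants: `u_I = 1 − (Δ_P + Δ_N)/(P(POS) + P(NEG))` (0 when
  nothing is decided) and `u_D = 1 − δ_B` (1 when nothing is deferred);
* accuracy–generality variant: the raw accuracy and generality values,
  degrading to (0, 0) when accuracy is undefined.

These functional forms are this package's own definitions (the literature
describes the players but leaves the payoffs to per-application choices);
they are pluggable via `build_game(..., payoff=...)`.

Pure Nash equilibria are enumerated by directly checking every profile
against all unilateral deviations.  Among multiple equilibria the selected
one maximizes the payoff sum, then minimizes total threshold movement,
then takes lexicographic strategy order — fully deterministic.  The
repeated game starts at (1, 0), making the Pawlak model the starting
point, and stops when (a) the selected profile is (stay, stay) or no pure
equilibrium exists, (b) the selected payoff sum improves by less than
1e-6, (c) the next thresholds would be infeasible, or (d) the iteration
cap (default 50) is hit — so termination is guaranteed and every returned
pair is feasible.  Because the search is myopic (it only sees one step
ahead), a weak-signal table whose best blocks sit below `1 − max(step)`
can legitimately leave the learner at (1, 0) with nothing decided.

## Iterative refinement with evolving features

Region quality is measured by precision: `Q_P = P(C|POS)`,
`Q_N = P(C^c|NEG)` (other measures could be slotted in).  An empty region
has undefined precision and fails any positive floor: an empty positive
region carries no evidence of adequacy, so the algorithm falls back to a
full recomputation.  Defaults `c1 = c2 = 0.9`; values above 1 are allowed
and act as an explicit "always recompute" switch (`evolve` also exposes
`force_full=True`).  On the boundary-only branch, thresholds are re-learned
on the reduced table whose universe *is* the old boundary — including the
region probabilities entering Δ — the boundary is re-trisected, the kept
POS/NEG absorb the new sub-regions, and the new boundary is the
sub-boundary itself.  Consequently POS and NEG can only grow and BND can
only shrink on that branch, which is asserted on every call.

## Evaluation

Accuracy is the correct fraction among decided objects (undefined, never
silently 0, when nothing is decided); generality is the decided fraction.
Held-out objects are classified by matching their (train-discretized)
signature to a training block and inheriting its region decision; an
unseen signature defers, which is exactly the intended semantics of
"insufficient evidence".  Cross-validation uses stratified folds (by
concept membership) from a required seed; per-fold test accuracy counts
only decided test objects, test generality is the decided fraction, and
folds with no decided objects are excluded from the accuracy mean with a
reported count.  Both train-side and held-out numbers are available; the
CV report is the held-out one.

## Synthetic data

The generator emulates an annotation problem with evolving features.  A
latent binary concept is drawn at a stated prevalence; the observed
decision label is then flipped with probability `label_noise`.  Each
categorical feature has one marker level per class plus uniform background
levels: with probability equal to its informativeness the value is the
marker of the object's *true* class, otherwise a background draw.  The two
effective class-conditional multinomials therefore overlap by exactly
`1 − informativeness`: informativeness is the fraction of objects for
which the feature is decisive, not a shift in a shared distribution.
Numeric features follow the same mixture with class-shifted Gaussians and
go through the standard discretizer, keeping one generation path.  Ground
truth (pre-noise labels) is returned alongside, never embedded in the
table.

The default evolving benchmark uses n = 1000 objects, prevalence 0.4,
label noise 0.1, and four cumulative groups of one ternary feature each
with informativeness 0.2 / 0.4 / 0.6 / 0.8 (seed 7).  One feature per
group keeps the full signature space at ≤ 3⁴ = 81, far below n, so
cross-validated generality is driven by how much probability mass the
learners decide, not by test signatures missing from the training folds.
Marker blocks have label-noise-limited purity (≈ 0.9) at *every* stage
while the share of marked objects grows with informativeness — which is
why generality ramps up across feature sets while decided-case accuracy
stays level, the qualitative phenomenon the trend test asserts over ten
benchmark seeds.  What passing that test shows is that the learners
track maturing information; it does not show calibration against any real
annotation corpus, whose feature distributions (heavy-tailed counts,
correlated features, hierarchical labels) the generator deliberately does
not imitate.

## Numerical and scale choices

Tie-breaks, block ordering (lexicographic by signature) and fold seeding
are all deterministic; identical inputs and seeds give identical outputs,
byte for byte.  Property tests run on random tables of up to 12 objects
and 3 attributes, where exhaustive oracles (dense-grid Δ minimization,
double-loop best-response enumeration, scripted replay of the repeated
game) are exact; the trend test uses the default benchmark at 10 CV folds
by 10 seeds by 5 models, sizes at which the whole suite completes in
about a minute on one CPU.

## Known limitations

* Only pure-strategy equilibria in 2-player games; a game with no pure
  equilibrium halts threshold movement rather than mixing.
* The concept is binary; multi-class uncertainty (non-binary entropy) is
  out of scope, as is any fuzzy or interval trisection.
* Exact signature matching for held-out objects is brittle when the
  signature space approaches the sample size; generalization across
  unseen signatures is deliberately refused (deferred), not smoothed.
* Feature *extraction* is out of scope: attributes arrive as table
  columns, and no external biological databases are consulted.
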