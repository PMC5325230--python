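# triway — three-way decisions with probabilistic rough sets

`triway` classifies the objects of an information table three ways —
**accept**, **reject** or **defer** — instead of forcing a binary call.  It
is aimed at settings like protein function annotation, where the evidence
describing each object (sequence length, localizations, interactor counts,
domains, …) arrives incrementally as biology's databases mature: objects
with insufficient evidence are *deferred*, and deferred cases shrink as new
features arrive.

## The model

An information table `S = (U, At, {V_a}, {I_a})` assigns every object a
value per attribute.  An attribute subset `A` groups objects into
equivalence classes `[x]`; for a concept `C` (the objects carrying a target
decision label) each class has a conditional probability
`P(C|[x]) = |[x] ∩ C| / |[x]|`.  A threshold pair `0 ≤ β < α ≤ 1` trisects
the universe:

    POS(α,β)(C) = {x : P(C|[x]) ≥ α}      → accept
    NEG(α,β)(C) = {x : P(C|[x]) ≤ β}      → reject
    BND(α,β)(C) = {x : β < P(C|[x]) < α}  → defer

`(α,β) = (1,0)` is the classical Pawlak model.  Two families of learners
choose the thresholds from data:

* **ITRS** (information-theoretic) minimizes the probability-weighted
  region uncertainty `Δ(α,β) = Σ_R P(R)·δ_R`, with `δ_R` the Shannon
  entropy (`itrs_e`) or Gini coefficient (`itrs_g`) of the concept split
  inside region R.  Δ is piecewise constant between block probabilities,
  so an exhaustive candidate-grid search finds the exact optimum.
* **GTRS** (game-theoretic) plays a repeated two-player game: one player
  may lower α, the other may raise β, each profile is scored by a payoff
  pair — immediate-region vs deferred-region uncertainty (`gtrs_e`,
  `gtrs_g`) or accuracy vs generality (`gtrs_ag`) — and the selected
  pure-strategy Nash equilibrium moves the thresholds until no profitable
  move remains.

When a **new feature arrives**, an iterative algorithm either re-trisects
only the previous boundary (when the decided regions' precisions clear
quality floors `c1`, `c2`) or recomputes everything from scratch.  Fitted
trisections are scored by accuracy (correct fraction among decided
objects) and generality (decided fraction of the universe), including
stratified k-fold cross-validation with signature-matched held-out
classification (unseen signatures defer).

## Worked example

The package ships the 8-protein demonstration table (three attributes
becoming available at times t0 < t1 < t2, decision "Function"):

```python
from triway import table1_fixture, ThreeWayModel, fit_evolving
from triway.refine import QualityConfig

table = table1_fixture()
res = ThreeWayModel(table, "Yes", "itrs_e",
                    attrs=("Localization", "Interacting proteins")).fit()
print(res.summary())
```

```
Three-Way Decision Results
============================================
method:            itrs_e
concept:           Function = Yes
attributes:        Localization, Interacting proteins
objects:           8
(alpha, beta):     (1, 0)
--------------------------------------------
|POS| (accept):    2
|NEG| (reject):    3
|BND| (defer):     3
accuracy:          1.0000
generality:        0.6250
uncertainty Delta: 0.3444 bits (shannon)
============================================
```

With only two attributes, ITRS keeps the Pawlak thresholds (1, 0): proteins
O3 and O6 are accepted, O4/O5/O7 rejected, and O1/O2/O8 deferred — 62.5% of
the universe is decided, all of it correctly, and the deferred boundary
carries 0.3444 bits of weighted uncertainty.  Feeding the features in one
at a time runs the iterative refinement algorithm:

```python
evo = fit_evolving(table, "Yes",
                   [["Localization"], ["Interacting proteins"], ["No. of Domains"]],
                   "pawlak", QualityConfig(0.9, 0.9))
print(evo.summary())
```

```
                                     feature_set         branch  pos  neg  bnd  accuracy  generality
                                    Localization        initial    0    0    8       NaN       0.000
               Localization+Interacting proteins full-recompute    2    3    3       1.0       0.625
Localization+Interacting proteins+No. of Domains  boundary-only    3    5    0       1.0       1.000
```

The boundary shrinks 8 → 3 → 0 as information matures; the final stage
re-trisects only the three deferred proteins (branch `boundary-only`)
because the decided regions already meet the 0.9 precision floors.

The same operations are available from the shell via the `triway` command
(`regions`, `learn-thresholds`, `evolve`, `evaluate`, `simulate`); see
`triway --help`.

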