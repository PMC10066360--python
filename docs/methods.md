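# Methods

## Data model and game rules

A game is a triple (configuration, group assignment, allocation log). The
configuration fixes the player count, group sizes, round count, identical
initial token endowment, and whether self-giving is allowed; the standard
design is 14 players in two groups of 7, 40 rounds, 40 tokens each,
self-giving allowed. Each round every player allocates exactly one token,
so the log is a function (round, giver) → receiver; it is stored internally
as a dense (rounds × players) receiver-index array, which encodes the
one-allocation-per-giver-per-round rule structurally and keeps
10,000-replicate Monte-Carlo loops cheap. Allocation order within a round
is treated as irrelevant (a round is a simultaneous move set). Validation
rejects duplicate (round, giver) pairs, unknown ids, missing allocations,
and self-giving when disallowed. Mid-game group changes, per-player rate
limits other than one-per-round, and unequal endowments are out of scope.

The central derived object is the cumulative exchange matrix `Y` at round
t: entry (i, j) counts tokens i received from j up to and including t
(receiver-row, giver-column, self-giving on the diagonal). Every giver's
column sums to t; token balances are `initial − t + row sum` and are
conserved at `n_players × initial` exactly.

## Dyadic regression

For each round t the design has one row per ordered pair (i, j), i ≠ j —
182 rows for 14 players — with response `Y_ijt`, regressors `Y_jit`
(reversed count), `G_ij` (1 = different groups) and their product. Exactly
two groups are required, since `G` is a binary different-group dummy; the
group *labels* never enter, so relabelling the groups leaves every estimate
unchanged. Self-pairs are excluded: reciprocity and favouritism are
undefined for i = j.

Estimation is ordinary least squares with no distributional assumption on
the error. Single fits use a QR least-squares solve; trajectories (one fit
per round) share the pair index and group dummy across rounds, so all
rounds are solved with one stacked normal-equations solve, falling back to
the minimal-norm least-squares solution when a round's design is singular.
Rank deficiency — possible in the earliest rounds, where the reversed-count
column has little variation — is flagged per round rather than handled by
dropping terms, so trajectories keep a fixed term set. R² is `1 − SSR/SST`
about the response mean; a zero-variance response (e.g. a round where
everyone self-gave) yields NaN with a `degenerate` flag, never an abort, so
a single pathological round cannot destroy a trajectory. The stacked and
single-fit paths agree to ~1e-9; both agree with an independent
pseudo-inverse oracle to 1e-10 in the tests. Row order affects estimates
only at floating-point rounding level (≤1e-10), which is the tolerance the
permutation-invariance test uses.

Classical standard errors and p-values are deliberately not reported: with
each giver constrained to one token per round the 182 observations are
dependent, and that inference would be invalid. All inference is delegated
to the null comparison below.

## The giving-at-random null and Monte-Carlo inference

The null agent picks a receiver uniformly over all n players *including
itself* each round; the expected cumulative count for any ordered pair at
round t is therefore t/n, and the expected received-source proportions for
two groups of 7 are 6/14 (ingroup), 7/14 (outgroup), 1/14 (self). A null
reference distribution is built by simulating K such games and fitting the
chosen variant at the requested rounds; K = 10,000 is the full budget,
1,000 the documented fast mode. Reference bands are empirical central
quantiles using a nearest-order-statistic rule (index = round(q·(K−1)),
half up, no interpolation) so that bands are bit-reproducible given a seed.
The p-value is the two-sided add-one empirical form
`min(1, 2·min[(1+#{draw ≤ obs})/(K+1), (1+#{draw ≥ obs})/(K+1)])`: strictly
positive, floor 2/(K+1), capped at 1. One-sided conventions were rejected
because the direction of an effect is not fixed a priori for every term.
No multiple-testing adjustment is applied across rounds or terms; cells are
reported individually.

Calibration: by construction, a null game compared against an independent
null reference lands outside the 95% band in ≈5% of (term, round) cells;
the acceptance checks verify this at K = 1,500 references and 300 games
(the empirical-band coverage bias is O(1/K) and invisible at that scale).

## Replacement-based influence

To measure a player's influence on the fitted ρ and γ trajectories, the
player is *replaced* by a null agent — their allocations re-drawn uniformly
each round, memorylessly, everyone else's kept verbatim — rather than
removed, because removal changes the structure of the data (the remaining
players would have given unequal token totals). For each player i and
replicate k, the additive model is refitted over all rounds and the L1
distance between original and altered coefficient vectors is recorded; the
influence metrics are the replicate means, one per coefficient. Both are
standardised by their across-player average, so standardised scores average
exactly 1 per game by construction (flagged players included in the
average), and values above 2 — strictly — are flagged. The additive variant
is fixed for influence because it is the variant whose trajectories the
rest of the analysis interprets. The full replicate budget is N = 10,000
per player; tests and the acceptance script use 60–300, which is ample
because the locked-pair fixture separates flagged scores from the rest by
an order of magnitude. A single-player mode returns the per-round mean and
95% bounds of the altered coefficients for trajectory overlays.

## Synthetic fixtures: what they emulate and what they do not

* **TOY-4**: a fixed 4-player, 3-round game whose exchange matrix, group
  means and regression coefficients are hand-countable (γ̂ = −1, ρ̂ = 17/41
  by the normal equations on 12 rows); it anchors every deterministic test.
* **Null game**: the study-scale giving-at-random game.
* **Locked pair**: null background with players 3 and 8 (different groups)
  overridden to give to each other every round — an extreme reciprocal
  outgroup dyad whose mutual counts equal t at every round.
* **Ingroup-biased agents**: every player weights receivers (self 1,
  ingroup 3 by default, outgroup 1). Strength 3 puts the final-round group
  coefficient near −3, far below the null 2.5% band (≈ −0.5), so detection
  power is essentially 1 at 40 replicates; strength 1 recovers the null,
  and the effect is monotone in the weight.
* A **reciprocator** agent (gives to its largest giver so far, ties random,
  uniform fallback) supports recovery tests.

These generators emulate the constraint structure and the two norms of
interest, not human behaviour: real players react to the displayed history
in ways no fixed policy captures (drift, imitation, punishment), and real
games mix heterogeneous policies. Passing tests therefore demonstrate that
the estimator and diagnostics behave correctly under known generating
processes — calibration under the null, detection at a stated effect size —
not that any particular behavioural claim holds in human data.

## Numerical and design choices

* Uniform-over-n *including self* is forced by the t/n expectation for the
  replaced player's pairs; excluding self would give t/(n−1).
* All randomness flows from one master seed through named substreams
  (null:k, replace:k, agent:k, influence:(player,k), layout), so replicate
  sets are reproducible and order-independent.
* Replicate budgets in the test-suite and acceptance script (10,000 for
  pure simulation summaries; 1,500/300 for calibration; 200–300 per player
  for influence; 40 games for power) were sized so each check's Monte-Carlo
  error is several times smaller than the margin it verifies.
* Network view: undirected edge weight is the two-direction sum of the
  final exchange matrix (the directed matrix stays available upstream);
  self-giving is a node attribute, not a loop edge; node size defaults to
  the mean of the two standardised influence scores (max available as an
  option); layout is Fruchterman–Reingold with edge weight as attraction,
  seeded for determinism.

## Known limitations

* Exactly two groups are supported in the regression (binary `G`); more
  groups would need a different coding.
* The early-round fits can be rank-deficient or degenerate; flags make this
  auditable but the trajectory values at those rounds should be read with
  care.
* Empirical p-values are limited below by 2/(K+1); reporting "< 0.001"
  requires K ≥ 2,000.
* The influence metric couples players through its standardisation: one
  extreme player deflates everyone else's standardised score.
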