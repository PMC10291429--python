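# Methods

This note records the model, the conventions, and the design choices behind
`hierdyn`, in enough detail to reproduce or audit every number the package
computes.

## The society model

A society is an ordered roster of `n` individuals (default 30), index 0
being the highest-ranking. Time advances in discrete updates; at each
update:

1. **Reproduction.** One member is chosen to reproduce. Without a rank
   effect, uniformly; with a rank effect, with probability proportional to
   `w(s) = 1 + c·s`, where `s = (n − p)/(n − 1)` is the standardized rank of
   position `p`. Reproduction is asexual and sex is ignored, so the model is
   best read as describing females and philopatric males.
2. **Placement.** The newborn is inserted according to the inheritance
   regime:
   - *MRI-YA* (maternal rank inheritance, youngest ascendancy): directly
     below the mother — hence above all older siblings, and never above the
     mother.
   - *Primogeniture*: directly below the youngest living older sibling, or
     directly below the mother if there is none, so older siblings outrank
     younger ones.
   - *Correlation*: directly above or directly below the mother with equal
     probability; parent and offspring rank always differ by one position.
   - *None*: uniformly over the `n + 1` insertion slots.
3. **Mortality.** One of the `n` pre-existing members dies, uniformly at
   random; the group returns to size `n`.

Births precede deaths within an update and the newborn is exempt from the
death draw of its own birth update. The model itself does not fix this
order; we chose birth-first-with-newborn-exemption because it keeps group
size exactly constant and treats the update as a single recruitment event.
The alternative (newborn eligible to die immediately) differs only by a
rare instant death (probability `1/(n+1)` per update) that contributes no
transition to any fitted chain, since such an individual is never observed
in two consecutive snapshots.

Founders are mutually unrelated and start in a uniformly random order.
Mortality is rank-independent throughout; group size, dispersal, and fission
are fixed or absent by design.

**Scale of the experiments.** Each condition runs 100 replicates of 1200
updates. The first 200 updates of each replicate are discarded as burn-in
before chain fitting, so that fitted transitions reflect the society's
stationary regime rather than the unrelated founder configuration; the
remaining panel pools roughly 2.9 million transitions per condition, ample
for an 11-state chain. Replicate count, updates, and burn-in are all
configurable; whether the original analyses discarded a burn-in is not
something the model's description fixes, so ours is an explicit,
documented default.

**Randomness.** Every replicate gets an independent PCG64 stream spawned
deterministically from the experiment seed and replicate index; pipeline
stages likewise spawn named streams from the master seed. Identical seeds
give bit-identical records, manifests, and checksums.

## Active/passive decomposition

For an individual present in consecutive observations of a hierarchy, the
total change in standardized rank splits as `total = active + passive`:

- **active** = `(a⁺ − a⁻) / (n_{t+1} − 1)`, where `a⁺` counts co-present
  group-mates that were above the focal individual before and below it
  after, and `a⁻` the reverse. Only dyads present in both periods can be
  reversed; the later period's group size anchors the conversion to
  standardized units (the change is expressed in the units of the year in
  which it is observed).
- **passive** = total − active, the demographic remainder.

Consequences used as test oracles: active sums to zero over co-present
individuals (every reversal has a winner and a loser); with constant
membership passive is identically zero; individuals observed in only one
period contribute nothing. Component-only trajectories are rebuilt by
accumulating one component's deltas from the starting position, clamping to
[0, 1] — a single component taken alone can leave the feasible range, and
the clamp is our documented handling. A singleton group's only member has
`s = 1` by convention.

The fixture generator builds hierarchies from structurally separated edits —
disjoint adjacent-pair swaps (purely active; a swap counts only if both
members survive the period) and removals plus insertions of new ids (purely
passive) — so its construction log is an exact ground-truth decomposition,
independent of the decomposition code it tests.

## Markov chains of hierarchy position

Positions are binned into deciles by `min(⌊10·s⌋ + 1, 10)`; at `n = 30`
each decile holds exactly three positions. In queen mode the top position
becomes an eleventh state above decile 10. Chains are fitted by maximum
likelihood: pooled lag-1 transition counts over each individual's recorded
tenure (post burn-in), row-normalized. A state never observed as a source
gets a self-loop and a warning rather than an invented uniform row; at the
default scale this cannot occur. Death truncates a sequence — there is no
death state — which is why queenship is absorbing under maternal rank
inheritance: the only exits from the top position are death (truncation)
or displacement, and under MRI-YA and primogeniture no newborn can ever be
inserted above the queen, so `P[Q,Q] = 1` exactly in the fitted chain.
Under the correlation regime the queen's own offspring displaces her half
the time she reproduces, and `P[Q,Q] < 1`.

Steady states follow the matrix-power recipe: multiply the matrix by itself
(one extra power per iteration, capped at 10⁵) until every entry changes by
less than ε = 0.001. If the rows of the limit agree within ε the chain is
flagged ergodic and their average is the steady state; otherwise the
per-start rows are retained, the flag is false, and the row average is
reported alongside, labelled as such. At ε = 0.001 the fitted society
chains typically stop before the rows fully mix (the queen and top deciles
are sticky), so the reported distribution is the row-averaged limit — the
equal-weight mixture over starting states. The median long-run state is the
lowest state, in low-to-high order, whose cumulative probability reaches
0.5; on a distribution that is exactly uniform over ten deciles this
convention returns decile 5.

Trajectory summaries map a decile to its midpoint rank `(d − 0.5)/10` and
the queen to 1.0, then report the per-step mean and SD across simulated
sequences (10 000 sequences of 120 transitions per starting state at the
default scale; 120 updates approximates the recruitment events a group of
30 experiences over a 10-year reproductive lifespan).

## Reproduction weights and inequality

The per-update reproduction probabilities are `q_p = w_p / Σw` with
`w_p = 1 + c·s_p`. The linear form is this package's parameterization of a
rank effect on annual offspring production; the slope is not free — it is
calibrated by root-finding so that the Gini index of `q` across the `n`
positions equals 0.19, the inequality injected at every individual
reproductive step. At `n = 30` the calibrated slope is `c ≈ 2.460`; the
continuous-rank approximation `G = c/(6 + 3c)` puts the root near 2.65,
a useful independent cross-check on the discrete solution. The map
`c ↦ Gini(q(c))` is strictly increasing, zero at the origin, and bounded by
the Gini of the bare ranks, so targets outside that range are rejected.

The Gini index is the population form `G = Σᵢⱼ|xᵢ − xⱼ| / (2n²x̄)` without
the small-sample `n/(n−1)` correction; the choice is isolated in one
function. `G` is scale-invariant and bounded by `1 − 1/n`.

A hierarchy state's expected per-update reproductive output is the mean of
`q` over the positions the state contains (three per decile at `n = 30`);
the queen state maps to the top position's `q`. Expected lifetime
reproductive success of a trajectory of `L` transitions sums this quantity
over the `L` post-start states, so uniform weights give exactly `L/n` for
every trajectory — a conservation identity the tests assert. Counting the
post-start states (rather than `L + 1` including the start) is our
convention; it only shifts every trajectory by one step's worth of output.

For each society condition, one trajectory of `L = 120` transitions is
drawn from each of the 11 starting states of the fitted queen-mode chain,
lifetime expectations are computed per start, and the Gini is taken across
the 11 values — unweighted, treating the queen as one starting position
like each decile; occupancy-weighted aggregation would be a one-line
variant. Repeating this 10 000 times yields the per-condition Gini
distribution. All four inheritance variants in this comparison run with
rank effects on reproduction, since the question is how inheritance
transforms a fixed per-step inequality.

## What the simulations do and do not emulate

The simulator generates the idealized societies the analysis is about:
constant group size, uniform mortality, purely passive dynamics, a single
rank-reproduction law. It does not emulate empirical features such as
active rank reversals, coalitionary dynamics, variable group size,
rank-dependent mortality or dispersal, observation error, or irregular
census intervals. Passing tests therefore validate the pipeline's logic
and the model's internal predictions — not claims about any particular
animal population. Real longitudinal hierarchy tables (CSV with
`group, period, id, position`) are accepted by the same decomposition,
encoding, and fitting machinery, but no result shipped with the package
depends on external data.

## Numerical choices and degenerate inputs

- Steady-state tolerance ε = 0.001 (entrywise, consecutive powers);
  fixed-point residual `‖πP − π‖∞ < ε` is asserted whenever the ergodic
  flag is set.
- Calibration root-finding to 1e−9 in `c`; the per-step Gini then matches
  its target to well under 1e−6.
- Decile encoding rejects `s` outside [0, 1]; reconstruction rejects
  starting positions outside [0, 1]; Gini rejects negative, all-zero, or
  singleton inputs; chain fitting rejects inputs with no transitions.
- Absorbing means `P[state, state] == 1` exactly — a fitted probability of
  0.9999 is not absorbing, and in the maternal-inheritance conditions the
  fitted value is exactly 1 because escape from queenship is structurally
  impossible, not merely rare.
- Full-precision (`%.17g`) CSV floats and round-trip parsing keep write/read
  cycles lossless, so manifests can assert byte-identical reruns.

## Known limitations

- The linear reproduction law is a calibrated stand-in for an empirical
  rate function; only its per-step Gini, not its shape, is pinned down.
  Quantities that depend on the shape (notably the lifetime-RS Gini levels)
  carry a corresponding systematic uncertainty of a few hundredths.
- Under random placement the long-run decile distribution is symmetric
  around the middle of the hierarchy, so its weighted median sits on the
  5/6 boundary and single runs can return either value.
- Chains are first-order and time-homogeneous by design; individual
  heterogeneity and history dependence are outside the model.
- Expected (not realized) reproductive output: the analysis propagates
  per-update probabilities, not stochastic birth counts, and does not
  accumulate inequality across generations.
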