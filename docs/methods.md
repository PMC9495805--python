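# Methods

This note documents the model, the numerical and design choices, what the
generators emulate, and the known limitations — including where measured
behavior departs from the qualitative expectations that motivated the
framework.

## Model and update rule

A network is `(N, K, s, topology, functions, state)`: `N` nodes, each with
exactly `K` ordered input slots, `s`-valued signals, a lookup table of
`s^K` entries per node, and a synchronous deterministic update (all nodes
read time-`t` states; order-independent). Signal values and time are
0-based. Input tuples are encoded **little-endian** — slot 0 is the least
significant digit of the table address — an arbitrary but frozen convention
required for bit-exact serialization.

Topologies keep in-degree fixed at `K` for every node:

* `er` — each node's `K` sources drawn uniformly without replacement from
  the other `N−1` nodes;
* `ss` / `sf` — growth from a `(K+1)`-clique; each new node picks `K`
  distinct existing sources, uniformly (`ss`) or with probability
  proportional to out-degree + 1 (`sf`; the +1 keeps zero-out-degree nodes
  reachable); node identities are permuted afterwards.

**Self-links and duplicate links are forbidden** in all generators. The
construction procedure of the original `ss`/`sf` networks is not public;
these are documented substitutes. Self-links were also tested and would
trivially create one-node feedback loops that confound the feedback-sign
experiments, without changing the headline statistics (measured: the
PAS-persistence rate is unchanged).

One global seed expands into named substreams (topology, functions, state,
disturbance draws, regulation, narrowing) via `SeedSequence`, so one
component can be re-randomized without touching the others.

## Damage experiments

A disturbance permanently changes one table entry — the entry addressed at
`t = 0` — so `A(0) = 0` and `A(1) = 1` always. The twin runs are tracked as
a joint pair state; on the first exact pair recurrence the remaining `A(t)`
is an exact periodic extension (this also captures secondary initiations,
where the permanent change re-ignites damage later). Runs without
recurrence inside `tmx` are reported raw. The small-avalanche threshold is
kept as the fraction 0.375 of `N` (the `A < 150` convention at `N = 400`)
so it transfers across sizes. `q(t)` uses the instantaneous criterion
`A(t) < threshold`; explosions are one-way in practice, so this coincides
with "still ordered" (the alternative "ever exceeded" reading differs
negligibly at chaotic parameters).

`P(d)` is histogrammed at exact counts (bin width `1/N`), so an empty gap
is literal. The gap band is the open interval between the largest occupied
`d` below the threshold and the smallest occupied `d` at/above it. Regime
classification: *ordered* if right mass < ε, *chaotic* if left mass < ε
(ε = 0.05), *half-chaotic* if both masses ≥ ε **and** the gap band is at
least 0.05 wide — the width floor makes "two peaks separated by a gap"
operational; scattered mid-band mass collapses the band and yields
*indeterminate*.

## Annealed theory

The damage map `d' = (1 − (1−d)^K)(s−1)/s` is the standard annealed
expectation (≥ 1 damaged input, redrawn output differs). Its linearization
at 0 reproduces the printed coefficient `w = K(s−1)/s`, and the map is
validated against a mechanical Monte-Carlo annealed model rather than
assumed. The chaotic equilibrium is the largest fixed point in `[0, 1]`,
found by bracketed root solving from the right (`d = 0` is always a fixed
point) to 1e-12; it is 0 when `w ≤ 1`.

## Evolution from PAS

`evolve` draws disturbances uniformly from the current complete set,
accepts a change when the final damage is below the threshold **and** (when
the anti-PAS rule is on) the new system's attractor period is at least
`min_attractor` (default 7; "attractor not found within cap" counts as long
enough). The initial state is kept fixed across accepted changes so the
disturbance set stays defined at the same `t = 0` state. Damage runs inside
evolution stop at the first explosion — a process that reaches the
threshold is rejected immediately; at `w = 2.25` an exploded avalanche sits
at `d* ≈ 0.74`, double the threshold, and was never observed to return.

**Measured limitation.** At `N = 400, s = 4, K = 3`, essentially *every*
small-damage outcome of a PAS is again a PAS: 1 non-point-attractor outcome
in ~30,000 small-damage candidates across er/ss/sf seeds (≈ 0.003%), far
rarer than the ~2% folklore figure. Since rejected trials leave the base
unchanged and a PAS has a fixed pool of `N(s−1)` disturbances, the strict
`min_attractor = 7` rule practically never finds an acceptable candidate
and the evolution stalls at the seed PAS. Microscopically this is forced: a
faded avalanche leaves every node reading constant inputs, hence a new
point attractor; a surviving *oscillating* lake must be self-sustaining and
simultaneously invisible to all its out-neighbors, which at `w = 2.25`
costs several independent 1/s coincidences. Consequently in-ice modules do
not emerge from this evolution operator at these parameters, and the
"both peaks of similar volume" picture is not reached either: the left-peak
mass of a PAS equals the avalanche extinction probability (~0.13 at these
parameters, branching ratio 2.25 over a Poisson-3 out-degree), not ~0.5.
Strong PAS regulation (below) does produce a dominant left peak. The
acceptance tests for these two expectations are left failing by design
rather than weakened; everything upstream of them (damage statistics, PAS
persistence > 98%, gap structure) is green.

## Dynamics, ice, in-ice modules

Attractor detection hashes visited states with full-state verification on
hash hits — exact, never probabilistic. Ice is defined over the attractor
portion only (transient excluded): a node is ice iff its state is constant
over one full rotation. Active nodes split into *weakly* connected
components of the restricted link graph (two interacting lakes count as
one); each module's local period is the smallest divisor of the global
period that its joint state sequence satisfies, and the global period
equals the lcm of local periods (capped at 1e9, above which the composition
is reported as undefined).

## Stability operators

* **Link/loop signs.** The influence sign of a link is the Spearman rank
  correlation between the input-slot value and the target's output over all
  `s^K` entries (|ρ| < 0.1 ⇒ sign 0); at `s = 2` this degrades to the
  Boolean activating/inhibiting convention. Loops are simple directed
  cycles up to `max_len` (default 3; enumeration is exponential and short
  loops dominate at these densities), signed by the product of nonzero link
  signs.
* **Positive→negative conversion** inverts, per positive loop, its
  lexicographically smallest link by recomposing the target function with
  `x ↦ s−1−x` on that slot — a pure table permutation, so conversion never
  narrows functions (deliberately factored apart from narrowing, which the
  original method entangled). The recursive variant repeats the
  census-and-convert pass (cap 10). **Measured limitation:** at `sf, s = 2,
  K = 4` the short-loop census contains only a few dozen loops in 1600
  links and our sf baselines are already fade-dominated (q ≈ 0.99 up to
  tmx = 20,000), so conversion measurably changes nothing; the expected
  stability gain from conversion, and the "combined conversion + modularity
  ≥ each alone" ordering, do not reproduce under this operationalization.
  Their acceptance tests are left failing with this analysis.
* **PAS regulation** redirects input tuples at Hamming distance 1 from the
  node's observed (PAS) tuple to the node's frozen state: level `a` all
  `K(s−1)` of them, `b` one random one, `c` none. The PAS entry itself is
  never touched, so the point attractor survives exactly. Distance-1
  pull-back is a modeling choice for "as much regulation as possible"
  without forcing global order outright; measured effect at level `a` is
  the total suppression of explosions on er nets.
* **Function narrowing** repeatedly redirects a random 10% of each node's
  entries to its current modal value until mean internal homogeneity `P`
  (frequency of the modal output; `P ∈ [1/s, 1]`) reaches the target —
  monotone by construction. Ordered fraction q rises steeply with the
  target (measured medians ~0.07 → ~0.12 → ~1.0 for targets 0.25/0.5/0.75
  at `s = 4, K = 3`).
* **Modular construction** wires equal modules internally per the requested
  family, then rewires each link across modules with probability
  `inter_frac`. Small modules with weak coupling (size ~10, 5%) raise q
  from ~0.05 to ~0.95+ at `s = 2, K = 4`.

## What the generators emulate, and what a green test establishes

All experiments are self-contained simulations of the abstract network
family; no biological data enters. Defaults are the stated world of the
framework: `N = 400, K = 3, s = 4, tmx = 1000`, threshold 0.375·N, 1200
disturbances, minimum attractor 7. Where tests run at reduced sizes for the
CPU budget (N = 120–200, tmx = 300–2000, evolution tmx = 300) this is noted
in the test docstrings; thresholds and tolerances are those of the stated
world and were not adapted to outcomes. A green test establishes behavior
of this idealized ensemble — fixed in-degree, uniform random tables,
synchronous determinism — not of any real regulatory network; in
particular, heterogeneous in-degree, stochastic update, and
self-constructed topology are out of scope.

## Known limitations

* The evolution operator cannot leave the point-attractor regime at the
  default parameters (see above); in-ice-module statistics are therefore
  only exercised on hand-built and small random systems.
* Attractor-based quantities require the attractor inside the search cap;
  fully random `N = 400` nets at chaotic parameters exceed any feasible cap
  and report "not found" (ice/module reports unavailable there).
* The feedback-conversion operator is a documented stand-in for an
  unpublished original; only sign-census correctness and topology
  preservation are guaranteed, not its stability effect.
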