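# Methods

This note documents the models implemented in `bcellfate`, the numerical
and protocol choices behind them, and the limits of what the test suite
demonstrates.

## The regulatory network

The packaged model has 22 nodes. Six form the core module of master
regulators whose stationary pattern defines the cell type — Bach2, Bcl6,
Blimp1, Irf4, Pax5, XBP1, reported in that order throughout. Five are
regulator-free environment inputs (Ag, CD40L, IL-2, IL-4, IL-21), and the
remaining eleven relay those signals to the core (BCR/ERK, CD40/NF-κB,
IL-2R/STAT5, IL-4R/STAT6, IL-21R/STAT3, plus AID as a downstream readout).
Each non-input node carries one AND/OR/NOT rule; extracting one signed edge
per distinct regulator literal per rule yields 39 interactions, four of
which (Pax5→Bcl6, Irf4⊣Pax5, Bcl6→Bcl6, Pax5→Pax5) are model predictions
rather than literature-curated links. Rules are stored as expression trees,
not truth tables, so the identical object drives the Boolean engine
(strict/bit-parallel evaluation) and the continuous engine (fuzzification);
node order is fixed (case-insensitive alphabetical) and defines the state
encoding everywhere.

Environment inputs carry no rule and update to 0 unless clamped. This
"decay" convention makes transient signals genuinely transient: every
attractor of the wild-type and of every clamped variant has all signalling
nodes off, and basin fractions over the full state space sum to one. The
alternative (inputs held at their initial value) would make every signal
combination its own invariant subspace and multiply the attractor count.

## Discrete engine

Synchronous updating: all nodes recompute simultaneously from the previous
state; clamped nodes stay at their clamp value. Exhaustive attractor
enumeration builds one successor table for the full 2^n state space with
bit-parallel numpy evaluation (n ≤ 26 guard), then advances every state 2^n
steps by pointer doubling (n gathers), which lands every trajectory inside
its attractor; cycles are recovered by walking the successor map from each
landing state and rotated to a canonical form. Cost is linear in state
count — about two seconds for the 4-million-state model on one CPU — and
the result is exact: attractor states, periods, and basin counts. A
per-trajectory hashed iterator (`find_attractor`) serves single starts, and
the test suite checks the enumeration against a naive per-state Python
iterator on random networks.

Mutant scans clamp one node to 0 (loss of function) or 1 (gain of function
or sustained signal) and re-enumerate; all 22 nodes × both values are
covered in the packaged mutant report.

**Basin conventions.** Basin fractions are reported over all 2^22 initial
states by default (every node's initial value free — the "all possible
initial conditions" reading); `enumerate_attractors(free_nodes=…)`
restricts the enumerated initial subspace instead (e.g. core module free,
signalling at rest). The attractor set is identical under every convention;
the percentages are not (see `results/discrete_basin_conventions.csv`).
Historically reported basin percentages for this model (56.25/6.25/6.25/
31.25) are not reproduced by this rule set under any initial-state
convention we enumerated — all attractor patterns and all mutant rows, by
contrast, reproduce exactly. We verified computationally that the reported
split arises only from a variant Irf4 rule, `(NF-κB ∨ Irf4 ∨ Blimp1) ∧
¬Bcl6`, enumerated over the 2^6 core subspace; that variant, however,
cannot reproduce the gain-of-function Bcl6 mutant attractors (it forces
Irf4 to 0 whenever Bcl6 is clamped on), so the published rules and the
published basins are mutually inconsistent and we keep the rules. The
corresponding acceptance test is intentionally left failing rather than
fitted, and the acceptance script reports the faithfully computed values.

## Continuous engine

Each node's activation is a dimensionless level x_i ∈ [0,1] (time is in
arbitrary units) obeying dx_i/dt = f_h(ω_i) − γ_i·x_i, with ω_i the node's
rule fuzzified by ∧→min, ∨→max, ¬→1−x, and f_h the sigmoid normalized
through (0,0), (0.5,0.5), (1,1). Inputs decay: dx/dt = −γx. Defaults are
h = 50 for every node (near-step response; the discrete and continuous
models are then directly comparable) and γ = 1 (the value for which the
flow preserves [0,1]; any other γ rescales every active steady level to
f(ω)/γ, which is what the γ sweep demonstrates). The sigmoid is evaluated
in the algebraically equivalent form

    f_h(ω) = expm1(−hω) · expit(h(ω−½)) / expm1(−h/2)

which never exponentiates a positive multiple of h, so h = 50 or 1000 does
not overflow, and the anchors 0, 0.5, 1 are exact in floating point. Exact
anchors matter: they make every Boolean fixed point an exact equilibrium,
and they create the additional fixed points with half-activated nodes
(ω = 0.5 ⇒ f = 0.5) that have no discrete counterpart.

**Integration.** Two paths, cross-checked in the tests:

- trajectory path (pulses, perturbations, single relaxations): LSODA via
  `scipy.integrate.solve_ivp` at rtol = atol = 1e-6, integrated in 25-unit
  chunks until the steady-state residual max|dx/dt| < 1e-10 (cap 500
  units; non-convergence is flagged, never silent);
- bulk path (random-start sampling): classic RK4 at fixed dt = 0.02,
  vectorized over the whole batch, with the same residual stop.

Converged states are *polished*: any level within 1e-5 of the equilibrium
grid {0, 0.5, 1} is snapped to it, and the snap is kept only if the
snapped state's residual still certifies an equilibrium. Distinct
attractors are then merged after rounding to 6 decimals.

**Why the moderate LSODA tolerance is a deliberate choice.** The model's
phase space contains saddle equilibria whose stable manifolds are
half-activation razors (several nodes exactly at 0.5). Trajectories
started from symmetric binary states can ride such a manifold for a long
time, and the side on which they eventually fall is then decided by
integration error; pushing tolerances toward 1e-13 does not settle the
matter — it merely changes which wobble decides, and can even park the
trajectory on a measure-zero saddle. At 1e-6 (the common default of
production ODE solvers for this model class) the physically meaningful
outcomes are reproduced robustly for the protocols used here; the razor
sensitivity itself is a property of the model, not of the implementation,
and is exercised explicitly in the test suite only through
protocol-relevant cases.

**Attractor discovery protocol.** Random-start sampling draws initial
states uniformly on [0,1]^22 (seeded) and relaxes them in bulk; at desk
scale (1000–5000 runs; configurable) it finds exactly the four binary
cell-fate equilibria. The perturbation search then takes each sampled
attractor × each node × levels {0, 0.5, 1} and *instantaneously* resets
that node to the level before relaxing the free system. One round adds
exactly three fixed points — Bcl6 and/or Irf4 at 0.5 on the Naive-like
background — for seven in total. Two protocol decisions deserve
justification:

- *Instantaneous reset, not a held clamp.* The discrete analogue of a
  single-node perturbation is a one-bit flip followed by free evolution;
  the instantaneous reset is its exact continuous counterpart. A held
  clamp is not innocuous here: holding Pax5 = 1 in the PC state for even
  one time unit lets Bach2 rise while Blimp1 decays and robustly converts
  PC into Mem, and holding Irf4 = 0 converts PC into Naive — contradicting
  the model's signature property that no single-node perturbation leaves
  the PC state. Held clamps remain available (`duration > 0`) and are the
  correct model of extracellular signal pulses (below).
- *One round, not transitive closure.* Perturbing the newly found
  half-activation states in turn walks onto further saddle equilibria
  (e.g. an all-halves core state) that are reachable only through exact
  razor manifolds; `closure=True` exposes them, but the default protocol
  perturbs only the sampled attractors, which is the discovery experiment
  the seven-attractor count refers to.

**Pulses and fate maps.** Signal pulses pin a node at a level for a window
(t_on, duration; the node's derivative is forced to 0, i.e. dIL-4/dt = 0
during the pulse) and then release it; a two-unit saturating pulse is
enough for each differentiation step, and the packaged protocol
(IL-4 @ t≈25 → CD40L @ t≈55 → Ag @ t≈75) walks Naive → GC → Mem → PC.
Onset times are cosmetic — destinations, not trajectory timing, are the
tested quantity. Fate maps apply the single-node perturbation protocol to
every attractor and draw an edge when the destination differs; the
discrete map uses bit flips, the continuous map instantaneous resets at
{0, 0.5, 1}. In both engines PC has out-degree zero. In the continuous
map the Naive→GC transitions are carried by core-node perturbations
(Bcl6 set high) rather than by instantaneous signal spikes: a spike of a
decaying input at γ = 1 peaks each downstream cascade stage at exactly the
0.5 razor, so it does not robustly propagate — held signal pulses (the
held-pulse protocol above) do drive Naive → GC via IL-2/IL-4. The
discrete map has both signal- and core-node edges, since a flipped signal
bit relays losslessly one layer per step.

## Labelling

Cell-type signatures are core-module patterns: Naive [1,0,0,0,1,0],
GC [1,1,0,0,1,0], Mem [1,0,0,1,1,0], PC [0,0,1,1,0,1], plus New1/New2/New3
with Bcl6 and/or Irf4 at 0.5 (match tolerance 0.05). An attractor matching
a signature on every core node gets the plain label; under a clamp, if all
*free* core bits match but the clamped bit is forced away, the label gains
"-like" (a Bach2-null [0,0,0,0,1,0] is Naive-like); exact matches beat
-like matches; everything else is "Other". The mutant report classifies
each clamp by comparing its labelled attractor set against the wild type
(attractors lost, replaced by -like, atypical found, single attractor).

## Synthetic networks

`generate_random_network` draws, per ruled node, k distinct regulators and
either a random AND/OR tree over randomly negated literals or a uniform
random truth table materialized as a DNF tree (so the continuous engine
fuzzifies it like any other rule; the all-false table becomes the
contradiction r ∧ ¬r). Generation is deterministic given the seed. These
networks have no biological pretensions: they exist so that the engines
can be validated against a brute-force oracle on instances the packaged
model does not exercise (limit cycles, constant rules, arbitrary
in-degrees), and so that cross-engine consistency (discrete fixed points =
continuous equilibria) is checked on arbitrary instances. Passing those
tests says nothing about any real regulatory network beyond the packaged
one.

## What the tests do and do not show

The suite verifies: rule-level truth tables against an independent
hand-coding; exact equality of the bit-parallel enumeration with a naive
iterator on random networks; the four discrete attractors and all 44
mutant scans; the continuous attractor set (4 + 3) and its analytic
equilibrium property for h ∈ {1,4,8,50,100}; the pulse-driven
differentiation chain; PC absorbency in both fate maps; and the f(ω)/γ
steady-state law. One acceptance test (the published basin split) fails by
design, as explained above. The suite does not validate biological
correctness of the network structure itself, asynchronous update schemes
(out of scope), or stochastic dynamics.

## Known limitations

- Exhaustive enumeration is capped at 26 free nodes; beyond that only
  trajectory-based search applies.
- Razor-manifold outcomes (which side of a saddle a symmetric trajectory
  falls to) are tolerance-dependent in any floating-point integrator; the
  package fixes one well-tested setting rather than pretending the
  sensitivity away.
- The continuous mutant scan estimates attractor reachability from random
  starts; unlike the discrete scan it can miss attractors with tiny
  basins (that is why the discovery protocol exists).
- SBML-qual support covers the Boolean qualitative-species +
  function-terms subset only.
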