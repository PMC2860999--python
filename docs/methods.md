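# Methods

## Model overview

`sensopt` studies how an embodied agent should partition its sensory
space so that the sensory consequences of its own actions become
maximally predictable. The agent is a point in a bounded 2-D arena; its
sensory space is its position; its motor repertoire is eight
fixed-length translations at 45° spacing. Executing action *k* from
pose *p* displaces the agent by a length drawn from
N(step_length, σ_SL²), clipped at zero, along a heading
N(45°·k, σ_A²); a path crossing the wall is reflected specularly
(repeatedly if needed, capped at ten bounces, after which the agent
stops at the last interior point). Three canonical arenas are provided,
all with ≈ 20 × 20 step-unit bounding boxes: a circle, a square, and a
fixed 16-vertex irregular polygon (versioned in `env_sim.py`; changing
it changes every downstream result for that arena). Positions are
continuous; angles are measured counterclockwise from +x.

Behaviour is abstracted as a Markov decision process over
**microstates**: square lattice cells (default side 1/3 step unit, i.e.
one third of the smallest canonical step length) whose centres lie in
the arena. The per-action transition tensor is estimated by one long
random walk with uniformly random actions, stopping once 95 % of cells
have been the source of at least 500 actions; at the canonical scale
this takes ~1.6 M actions (≈ 560 per cell) and a few seconds. Cells
that end up with no samples for some action are dropped from the grid
(≈ 0.5 % of cells, border artifacts) and the remaining rows are
renormalized, so that activity propagation conserves probability mass;
the rare row whose observed successors were all dropped is completed
with a stay-in-place self-loop. Residual per-row leakage above 1 %
aborts with a diagnostics message rather than silently renormalizing a
poorly explored tensor.

**Macrostates** are disjoint sets of microstates. Their transition
probabilities follow from injecting unit probability mass uniformly
over the source state's members, propagating it one step along the
per-action microstate graph, and summing over each target state's
members — algebraically `TM_k = D⁻¹ Sᵀ tm_k S` for the membership
indicator `S` and size diagonal `D`.

## The objective and its components

- **Predictability** (per state): action-averaged Euclidean norm of the
  `TM` row — a sparseness measure equal to 1 for one-hot rows and 1/√n
  for uniform rows over n targets.
- **Decorrelation** (per pair): one minus the uncentred correlation of
  the two states' *propagated microstate-occupancy distributions*
  (the fine-grained pre-aggregation view), computed per action and
  averaged; per state, the minimum over all other states. Using the
  microstate-level distributions makes partial spatial overlap of two
  states' outcome regions register as similarity even when the coarse
  `TM` rows share no target state. The uncentred (not mean-free)
  coefficient keeps orthogonal distributions at exactly zero.
- **Self-connectivity** (per state): action-averaged diagonal of `TM`.
- **Ψ** (per state): `(β·pred + (1−β)·decorr) · (1 − self)`, β = 0.8.
  Configurations are ranked by the unweighted mean of Ψ.

## Optimization

Each iteration evaluates the current configuration, compiles candidate
lists, and applies one operation *type*:

- **merge branch** (taken when mean decorrelation < mean
  predictability): pairs are ranked by ascending pairwise
  decorrelation; a greedy pass accepts disjoint pairs, skipping any
  pair whose merged state's action-averaged self-connection would be
  its largest action-averaged transition probability (the brake that
  stops states from outgrowing the step length). Pairs with zero
  correlation are never merge candidates — combining states with
  orthogonal outcome distributions cannot improve either objective
  component.
- **cut branch** (otherwise): states below the median *cut score* are
  split in two by the Shi–Malik normalized cut of their members'
  projection-similarity graph (uncentred correlation of the
  microstate-to-macrostate transition vectors, per action, averaged).
  The spectral relaxation uses the second-smallest generalized
  eigenvector of (D−W, D) with a full scan over the sorted-eigenvector
  splits for the minimum Ncut; a disconnected similarity graph is
  instead split along its connected components, grouped into two sides
  of balanced total size. The cut score is `pred·(1−self)` rather than
  raw predictability: identical in the intended operating regime
  (self-connectivity near zero) but robust to very large states, whose
  self-transitions inflate the plain row norm and would otherwise
  shield exactly the states that most need cutting.
- If the merge branch is selected but every candidate is vetoed, the
  iteration falls back to cutting rather than idling. The reverse
  fallback is deliberately absent: merging during boundary-blocked cut
  phases collapses configurations prematurely.

An upper boundary on the number of macrostates cycles through
1000 → 500 → 10, switching every 20 iterations. The boundary blocks
cuts that would exceed it and, when the schedule drops below the
current count, *forces* merges (most-correlated disjoint pairs, veto
suspended) until the count complies. The forced coarsening and
subsequent re-refinement act as an annealing cycle: the best-Ψ
configurations typically appear mid-rebuild, tens of iterations after a
coarsening phase, and the per-iteration mean Ψ changes discontinuously
— which is why the run's result is the best configuration over the
whole trace, not the final one. Runs are initialized with a uniformly
random labeling into n ~ U{200..800} states.

The weighting β enters only the *selection* of the best iteration, not
the operations themselves, so stored traces (per-iteration, per-state
pred/decorr/self) can be re-scored for any β without re-running
anything. Below a critical β (≈ 0.31 measured here) the selection
degenerates to near-initial, highly decorrelated but unpredictable
configurations found within the first few dozen iterations.

## Spatial analysis

Area is the member count; solidity is area over the pixelated convex
hull area (`skimage.regionprops`, single cells score 1); eccentricity
comes from the moment-matched ellipse and roundness is 1 − eccentricity.
A spatially disconnected state is analysed as one region. Log-area
weighting (`x·ln area`) removes the trivially perfect scores of
singleton states from configuration summaries. Topographical similarity
of two configurations matches each state of the smaller configuration
to a state of the other by descending uncentred correlation of binary
occupancy maps, injectively (greedy, without replacement); equal-sized
configurations average both matching orientations so the measure is
exactly symmetric.

## Navigation

A navigation trial fixes a connected goal region (grown by random
breadth-first accretion to the size of the average optimized
macrostate) and a start cell outside it. Planning runs Dijkstra on the
macrostate graph with edge cost `−ln(max_k TM[i,j,k])` (plus a 10⁻⁶
per-hop constant so deterministic edges still prefer short paths); each
state's action maximizes the transition probability to its next hop.
States overlapping the goal take the action that moves the most
probability mass into the goal cells. Closed-loop performance is
measured by propagating microstate occupancy — every cell uses its
macrostate's action — with the goal region absorbing; a trial ends when
the absorbed (goal-occupancy) probability reaches 0.95, with a 500-step
cap (capped trials are flagged, not counted as successes). Path
reproducibility is the Shannon entropy (nats) of the macrostate
occupancy of the renormalized circulating mass, averaged over the first
18 steps and compared between an optimized map and a control map with
the same number of states on the same start/goal pairs. Control maps
are winner-take-all partitions over N unit-amplitude isotropic
Gaussians (centres uniform over cells, σ ~ U(1.5, 4.0) step units;
empty labels redrawn individually).

## Sensory-only comparison and temporal stability

Collapsing the transition tensor along the action dimension (unweighted
mean of the eight per-action matrices — exploration draws actions
uniformly — then renormalized) removes motor identity while preserving
sensory transition structure. The collapsed tensor is optimized exactly
like the full one (all machinery is action-count agnostic) and the
resulting configuration is evaluated against the *full* tensor.

For stability analysis a discrete configuration is converted to
continuous place-field-like activities: an isotropic Gaussian is fitted
to the largest connected component of each state (centroid, RMS
radius), then per-cell activities are multiplicatively refined until a
winner-take-all over states reproduces the partition (fallback for
irrecoverable configurations: indicator maps smoothed with a one-cell
Gaussian, flagged). A motion generator alternates translation
(0.25 step units per time step) and rotation (15° per step) modes with
switch probability 0.1 per step and turns away from walls. Stability is
the slowness of the sum-normalized population activity along the
trajectory — per state, mean squared one-step change divided by
variance, averaged — normalized so a matched random configuration on
the same trajectory scores 1; 0 is perfect stability.

## Problem sizes used by the shipped analyses

The test suite's replication layer uses the circular arena at cell size
0.5 with one 400-iteration run per motor cell and 30 navigation trials;
`scripts/acceptance.py` uses the default resolution (cell 1/3), four
motor cells, 1000-iteration runs and 100 paired navigation trials.
Exact formula-level checks (aggregation identity, normalized cut vs
exhaustive search, occupancy propagation vs dense matrix powers, mass
conservation, bit-reproducibility under a fixed seed) run on ≤ 30-cell
fixtures in milliseconds and gate every change.

## What the synthetic setting does and does not show

The generator reproduces the study conditions exactly — the agent, the
arenas and the motor-parameter grids are the model system itself, not a
stand-in for external data — so "synthetic" here means simulated, not
approximated. What the shipped runs do *not* establish: behaviour at
microstate resolutions other than those tested (several objective
components are resolution-dependent, see below), robustness to
non-uniform exploration policies, and any claim about continuous-time
or visually-driven agents.

## Known limitations

- **Absolute objective magnitudes are scale-dependent.** Predictability
  and decorrelation depend on the microstate resolution and on the
  (unrecoverable) details of the original sparseness normalization; the
  values computed here are internally consistent and reproduce the
  *relations* between conditions (β transition, noise ordering, area
  scaling) more faithfully than the absolute levels.
- **Residual fragment states.** The coarsen/refine cycles leave a tail
  of very small states and a few large scattered ones in the best-Ψ
  configurations (median state size a few cells next to a mean of
  ~8–20). This depresses mean roundness, occasionally misleads the
  macrostate-level planner (navigation trials that time out are
  flagged), and makes the temporal-stability ratio of optimized
  configurations land slightly above 1 instead of below.
- **Sensory-only comparison.** Sensory-only optimization produces much
  larger states (consistent with the expected direction); at those
  sizes the Euclidean-norm predictability is inflated by
  self-transitions, so the full-tensor predictability difference
  between sensorimotor and sensory-only configurations comes out
  negative here rather than positive.
- The normalized-cut split is exact only in the spectral-relaxation
  sense; ties in the eigenvector scan are broken toward the first
  minimal split.
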