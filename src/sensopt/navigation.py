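"""Policy planning and closed-loop navigation on macrostate maps.

A navigation trial asks the agent to move probability mass from a start
microstate into a connected goal region.  Planning happens at the
macrostate level: transition probabilities define a directed graph with
edge cost -ln(max_k TM[i, j, k]), on which Dijkstra's algorithm yields,
for every macrostate, the action most likely to progress toward the
goal.  Navigation is then simulated in closed loop by propagating
microstate occupancy: each microstate's mass moves according to the
action its containing macrostate is mapped to; mass entering the goal
region is absorbed.  A trial ends when the absorbed (goal-occupancy)
probability reaches a threshold of 0.95, and the number of propagation
steps measures navigability.  The Shannon entropy of the macrostate
occupancy of the not-yet-absorbed mass measures how reproducible the
travelled state sequence is.

Control configurations — winner-take-all partitions over randomly
placed isotropic Gaussians — provide a baseline of solid, approximately
convex states whose placement is not optimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph

from .macrostates import MacrostateConfig, MacroTransitions, macro_transitions
from .microstates import Grid, TransitionModel

__all__ = [
    "ControlConfigParams",
    "Policy",
    "NavigationResult",
    "control_config",
    "plan",
    "simulate_occupancy",
    "sample_goal_region",
    "run_navigation_experiment",
]


@dataclass(frozen=True)
class ControlConfigParams:
    """Parameters of the random-Gaussian control partition."""

    n_states: int
    sigma_range: tuple[float, float] = (1.5, 4.0)

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")


def control_config(
    grid: Grid,
    params: ControlConfigParams,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> MacrostateConfig:
    """Winner-take-all partition over N randomly placed Gaussians.

    Centres are drawn uniformly over the grid cells, widths uniformly
    from ``sigma_range`` (step units).  Each cell is labelled by the
    Gaussian of largest density at its centre.  Draws leaving some label
    empty are rejected and repeated.
    """
    N = params.n_states
    if N > grid.n_cells:
        raise ValueError("more control states than grid cells")
    centers = grid.centers[rng.integers(0, grid.n_cells, size=N)]
    centers = centers + rng.uniform(-0.5, 0.5, size=(N, 2)) * grid.cell_size
    sig = rng.uniform(*params.sigma_range, size=N)
    for _ in range(max_retries):
        d2 = ((grid.centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        # unit-amplitude Gaussians: every state wins near its own centre,
        # which keeps the winner-take-all regions solid and convex-ish
        labels = np.argmax(np.exp(-d2 / (2 * sig[None, :] ** 2)), axis=1)
        present = np.zeros(N, dtype=bool)
        present[np.unique(labels)] = True
        if present.all():
            return MacrostateConfig(labels=labels)
        # redraw only the Gaussians that ended up with no cells
        empty = np.flatnonzero(~present)
        centers[empty] = grid.centers[rng.integers(0, grid.n_cells, size=len(empty))]
        sig[empty] = rng.uniform(*params.sigma_range, size=len(empty))
    raise RuntimeError(f"could not draw {N} nonempty control states in {max_retries} tries")


@dataclass
class Policy:
    """Macrostate-to-action map toward a goal set of macrostates."""

    action_of: np.ndarray  # (n_macro,) action index, -1 where unreachable
    goal_macros: np.ndarray
    reachable: np.ndarray  # (n_macro,) bool


def plan(
    TM: MacroTransitions,
    goal_macros,
    model: TransitionModel | None = None,
    config: MacrostateConfig | None = None,
    goal_cells: np.ndarray | None = None,
) -> Policy:
    """Most-probable-path policy via Dijkstra on -log transition costs.

    For every macrostate the next hop minimizes edge cost plus remaining
    distance to the goal set, and the assigned action is the one
    maximizing the transition probability to that hop.  A goal
    macrostate takes the action that moves the most probability mass
    into the goal cells when those are given (it may be much smaller
    than the state containing it), falling back to the state's most
    self-preserving action otherwise.  States that cannot reach the
    goal are flagged and keep action -1.
    """
    goal_macros = np.atleast_1d(np.asarray(goal_macros, dtype=int))
    n = TM.n_macro
    pmax = TM.TM[0].copy()
    for t in TM.TM[1:]:
        pmax = pmax.maximum(t)
    pmax = sparse.csr_matrix(pmax)
    pmax.setdiag(0.0)
    pmax.eliminate_zeros()
    cost = pmax.copy()
    # small per-hop constant so that deterministic edges (probability 1,
    # -log cost 0) still prefer shorter paths instead of degenerate ties
    cost.data = -np.log(cost.data) + 1e-6
    # distance from every node TO the goal set: run Dijkstra on the
    # reversed graph from the goal nodes
    dist = csgraph.dijkstra(cost.T, indices=goal_macros, min_only=True)
    action_of = np.full(n, -1, dtype=np.int64)
    reachable = np.isfinite(dist)
    coo = cost.tocoo()
    # for each source i, pick hop j minimizing cost(i, j) + dist(j)
    totals = coo.data + dist[coo.col]
    best = {}
    for i, j, v in zip(coo.row, coo.col, totals):
        if np.isfinite(v) and (i not in best or v < best[i][0] - 1e-15):
            best[i] = (v, j)
    probs = np.dstack([t.toarray() for t in TM.TM]) if n <= 2048 else None
    for i, (_, j) in best.items():
        if probs is not None:
            action_of[i] = int(np.argmax(probs[i, j]))
        else:
            action_of[i] = int(np.argmax([t[i, j] for t in TM.TM]))
    use_flux = model is not None and config is not None and goal_cells is not None
    if use_flux:
        goal_ind = np.zeros(model.n_cells)
        goal_ind[goal_cells] = 1.0
        flux_per_action = np.column_stack(
            [t @ goal_ind for t in model.tm]
        )  # (M, K) per-cell one-step mass into the goal region
    for g in goal_macros:
        if use_flux:
            members = np.flatnonzero(config.labels == g)
            action_of[g] = int(np.argmax(flux_per_action[members].mean(axis=0)))
        else:
            action_of[g] = int(np.argmax([t[g, g] for t in TM.TM]))
        reachable[g] = True
    return Policy(action_of=action_of, goal_macros=goal_macros, reachable=reachable)


@dataclass
class NavigationResult:
    """Outcome of one closed-loop occupancy simulation."""

    steps_to_criterion: int  # -1 if the threshold was not reached
    goal_prob_series: np.ndarray
    entropy_series: np.ndarray
    reached: bool


def _policy_matrix(
    model: TransitionModel, config: MacrostateConfig, policy: Policy, goal_cells: np.ndarray
) -> sparse.csr_matrix:
    """Microstate propagation matrix under the policy, goal rows removed."""
    M = model.n_cells
    actions = policy.action_of[config.labels]
    # unreachable macrostates: mass stays put (their action is undefined)
    P = sparse.csr_matrix((M, M))
    for k in range(model.n_actions):
        mask = actions == k
        if mask.any():
            P = P + sparse.diags(mask.astype(float)) @ model.tm[k]
    stay = actions < 0
    if stay.any():
        P = P + sparse.diags(stay.astype(float))
    P = sparse.lil_matrix(P)
    P[goal_cells, :] = 0.0  # absorbing goal region
    return sparse.csr_matrix(P)


def simulate_occupancy(
    model: TransitionModel,
    config: MacrostateConfig,
    policy: Policy,
    start_micro: int,
    goal_cells: np.ndarray,
    threshold: float = 0.95,
    max_steps: int = 500,
    min_steps: int = 0,
) -> NavigationResult:
    """Propagate occupancy mass under the policy until goal absorption.

    Unit mass starts at ``start_micro``; each step multiplies the
    circulating mass by the policy-conditioned transition matrix and
    absorbs whatever lands in the goal region.  The per-step entropy is
    computed over the macrostate occupancy of the renormalized
    circulating mass (in nats).  Propagation continues until the
    absorbed mass reaches ``threshold`` (and at least ``min_steps``
    steps were taken, so entropy series of fixed length can be
    compared), or until ``max_steps``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    goal_cells = np.asarray(goal_cells, dtype=int)
    if start_micro in set(goal_cells.tolist()):
        raise ValueError("start microstate lies inside the goal region")
    P = _policy_matrix(model, config, policy, goal_cells)
    act = np.zeros(model.n_cells)
    act[start_micro] = 1.0
    absorbed = float(act[goal_cells].sum())
    goal_series = []
    entropy_series = []
    S = None
    steps_to = -1
    step_i = 0
    while step_i < max_steps:
        act = act @ P
        gmass = float(act[goal_cells].sum())
        absorbed += gmass
        act[goal_cells] = 0.0
        goal_series.append(absorbed)
        circ = act.sum()
        if circ > 1e-12:
            occ = np.bincount(config.labels, weights=act, minlength=config.n_macro)
            p = occ[occ > 1e-15] / circ
            entropy_series.append(float(-(p * np.log(p)).sum()))
        else:
            entropy_series.append(0.0)
        step_i += 1
        if steps_to < 0 and absorbed >= threshold:
            steps_to = step_i
        if steps_to >= 0 and step_i >= min_steps:
            break
    return NavigationResult(
        steps_to_criterion=steps_to,
        goal_prob_series=np.array(goal_series),
        entropy_series=np.array(entropy_series),
        reached=steps_to >= 0,
    )


def sample_goal_region(
    grid: Grid, size: int, rng: np.random.Generator, adjacency: sparse.csr_matrix | None = None
) -> np.ndarray:
    """A connected goal region grown by random breadth-first accretion."""
    if adjacency is None:
        adjacency = grid_adjacency(grid)
    seed = int(rng.integers(0, grid.n_cells))
    region = {seed}
    frontier = set(adjacency[seed].indices.tolist())
    while len(region) < size and frontier:
        nxt = sorted(frontier)[int(rng.integers(0, len(frontier)))]
        frontier.discard(nxt)
        region.add(nxt)
        frontier.update(j for j in adjacency[nxt].indices.tolist() if j not in region)
    return np.array(sorted(region), dtype=int)


def grid_adjacency(grid: Grid) -> sparse.csr_matrix:
    """4-neighbour adjacency of the grid cells."""
    img = grid.id_of
    pairs = []
    for dr, dc in ((0, 1), (1, 0)):
        a = img[: img.shape[0] - dr, : img.shape[1] - dc]
        b = img[dr:, dc:]
        ok = (a >= 0) & (b >= 0)
        pairs.append(np.column_stack([a[ok], b[ok]]))
    ij = np.vstack(pairs)
    ij = np.vstack([ij, ij[:, ::-1]])
    return sparse.csr_matrix(
        (np.ones(len(ij)), (ij[:, 0], ij[:, 1])), shape=(grid.n_cells, grid.n_cells)
    )


def _goal_macros_for(config: MacrostateConfig, goal_cells: np.ndarray) -> np.ndarray:
    return np.unique(config.labels[goal_cells])


def evaluate_map(
    model: TransitionModel,
    config: MacrostateConfig,
    TM: MacroTransitions,
    start: int,
    goal_cells: np.ndarray,
    threshold: float = 0.95,
    max_steps: int = 500,
    entropy_window: int = 18,
) -> NavigationResult:
    """Plan toward the goal region on one map and simulate the trial."""
    goals = _goal_macros_for(config, goal_cells)
    policy = plan(TM, goals, model=model, config=config, goal_cells=goal_cells)
    return simulate_occupancy(
        model,
        config,
        policy,
        start,
        goal_cells,
        threshold=threshold,
        max_steps=max_steps,
        min_steps=entropy_window,
    )


def run_navigation_experiment(
    model: TransitionModel,
    grid: Grid,
    opt_config: MacrostateConfig,
    rng: np.random.Generator,
    n_trials: int = 100,
    ctrl_params: ControlConfigParams | None = None,
    threshold: float = 0.95,
    entropy_window: int = 18,
    max_steps: int = 500,
) -> pd.DataFrame:
    """Paired navigation trials on an optimized map and a matched control.

    Every trial samples a connected goal region of average-macrostate
    size and a start cell outside it, then evaluates both maps on the
    same start/goal.  The per-trial entropy ratio is the mean
    macrostate-occupancy entropy over the first ``entropy_window`` steps
    on the optimized map divided by the same quantity on the control
    map.
    """
    if ctrl_params is None:
        ctrl_params = ControlConfigParams(n_states=opt_config.n_macro)
    ctrl = control_config(grid, ctrl_params, rng)
    TM_opt = macro_transitions(opt_config, model)
    TM_ctrl = macro_transitions(ctrl, model)
    goal_size = max(1, int(round(opt_config.n_micro / opt_config.n_macro)))
    adjacency = grid_adjacency(grid)
    rows = []
    for trial in range(n_trials):
        goal = sample_goal_region(grid, goal_size, rng, adjacency=adjacency)
        outside = np.setdiff1d(np.arange(grid.n_cells), goal)
        start = int(outside[rng.integers(0, len(outside))])
        res_o = evaluate_map(
            model, opt_config, TM_opt, start, goal,
            threshold=threshold, max_steps=max_steps, entropy_window=entropy_window,
        )
        res_c = evaluate_map(
            model, ctrl, TM_ctrl, start, goal,
            threshold=threshold, max_steps=max_steps, entropy_window=entropy_window,
        )
        ent_o = res_o.entropy_series[:entropy_window].mean()
        ent_c = res_c.entropy_series[:entropy_window].mean()
        rows.append(
            {
                "trial": trial,
                "steps_optimized": res_o.steps_to_criterion,
                "steps_control": res_c.steps_to_criterion,
                "reached_optimized": res_o.reached,
                "reached_control": res_c.reached,
                "entropy_optimized": ent_o,
                "entropy_control": ent_c,
                "entropy_ratio": ent_o / ent_c if ent_c > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
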