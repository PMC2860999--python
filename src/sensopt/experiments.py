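"""Study-level orchestration: sweeps, collapse comparison, stability.

These routines reproduce the package's headline analyses:

* motor-parameter sweeps — repeat exploration + optimization across
  step-length and noise grids and aggregate objective/region statistics;
* beta re-selection — the weighting beta enters only the *selection* of
  the best iteration, so stored traces can be re-scored for any beta
  without re-running the optimizer; below a critical beta the selection
  degenerates to near-initial, low-predictability configurations;
* sensory-only collapse — optimizing on the action-averaged transition
  tensor (motor identity discarded) and evaluating the result against
  the full tensor quantifies the value of knowing one's actions;
* temporal stability — macrostate configurations are converted to
  continuous place-field-like activity maps and scored by how slowly
  the population activity changes along a naturalistic
  translation/rotation trajectory, normalized so a matched random
  configuration scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse

from .env_sim import Maze, MotorParams, make_maze
from .macrostates import MacrostateConfig, macro_transitions, random_config
from .microstates import (
    DEFAULT_CELL_SIZE,
    Grid,
    TransitionModel,
    build_grid,
    explore,
    normalize_counts,
    restrict_to_sampled,
)
from .objective import ObjectiveParams, evaluate
from .optimizer import OptimizationTrace, OptimizerSettings, optimize
from .spatial import region_stats, size_weighted

__all__ = [
    "SweepSpec",
    "StabilityParams",
    "build_tensor",
    "parameter_sweep",
    "beta_sweep",
    "critical_beta",
    "sensory_only_collapse",
    "optimize_sensory_only",
    "config_to_place_fields",
    "stability_eval",
]


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def build_tensor(
    maze: Maze | str,
    mp: MotorParams,
    cell_size: float = DEFAULT_CELL_SIZE,
    min_visits: int = 500,
    coverage: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[TransitionModel, Grid, Maze]:
    """Explore one maze/motor-parameter combination.

    Returns the transition model and grid restricted to the sampled
    cells (see :func:`sensopt.microstates.restrict_to_sampled`).
    """
    if isinstance(maze, str):
        maze = make_maze(maze)
    if rng is None:
        rng = np.random.default_rng()
    grid = build_grid(maze, cell_size)
    model = explore(maze, mp, grid, min_visits=min_visits, coverage=coverage, rng=rng)
    model, grid = restrict_to_sampled(model, grid)
    return model, grid, maze


@dataclass
class SweepSpec:
    """Factorial sweep over mazes and motor parameters."""

    mazes: tuple[str, ...] = ("circular", "square", "irregular")
    step_lengths: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    sigma_sls: tuple[float, ...] = (1 / 15, 2 / 15, 3 / 15)
    sigma_as: tuple[float, ...] = (2.0, 6.0, 12.3)
    runs_per_cell: int = 5
    cell_size: float = DEFAULT_CELL_SIZE
    min_visits: int = 500
    coverage: float = 0.95
    settings: OptimizerSettings = field(default_factory=OptimizerSettings)
    seed: int = 0


def parameter_sweep(spec: SweepSpec, keep_traces: bool = False):
    """Run the sweep; returns a per-run results table (and traces).

    Each row holds the best configuration's objective scores and region
    statistics.  Traces are only retained on request (they are large).
    """
    rows = []
    traces = []
    cell_id = 0
    for maze_kind in spec.mazes:
        for sl in spec.step_lengths:
            for ssl in spec.sigma_sls:
                for sa in spec.sigma_as:
                    mp = MotorParams(step_length=sl, sigma_sl=ssl, sigma_a_deg=sa)
                    model, grid, _ = build_tensor(
                        maze_kind,
                        mp,
                        cell_size=spec.cell_size,
                        min_visits=spec.min_visits,
                        coverage=spec.coverage,
                        rng=_rng_for(spec.seed, 0, cell_id),
                    )
                    for run in range(spec.runs_per_cell):
                        trace = optimize(
                            model, spec.settings, rng=_rng_for(spec.seed, 1, cell_id, run)
                        )
                        rows.append(
                            summarize_run(trace, model, grid)
                            | {
                                "maze": maze_kind,
                                "step_length": sl,
                                "sigma_sl": ssl,
                                "sigma_a": sa,
                                "run": run,
                            }
                        )
                        if keep_traces:
                            traces.append(trace)
                    cell_id += 1
    table = pd.DataFrame(rows)
    return (table, traces) if keep_traces else table


def summarize_run(trace: OptimizationTrace, model: TransitionModel, grid: Grid) -> dict:
    """Objective and region statistics of a run's best configuration."""
    cfg = trace.best_config
    rep = evaluate(macro_transitions(cfg, model), ObjectiveParams())
    stats = region_stats(cfg, grid)
    return (
        rep.summary()
        | size_weighted(stats)
        | {"best_iter": trace.best_iter, "best_psi": trace.best_psi}
    )


# ---------------------------------------------------------------------------
# Beta sweep


def beta_sweep(traces: list[OptimizationTrace], betas) -> pd.DataFrame:
    """Re-select the best iteration of each stored trace for every beta."""
    rows = []
    for b in betas:
        for run, trace in enumerate(traces):
            it, rec = trace.reselect(float(b))
            rows.append(
                {
                    "beta": float(b),
                    "run": run,
                    "selected_iter": it,
                    "pred": rec.mean_pred,
                    "decorr": rec.mean_decorr,
                    "self_conn": rec.mean_self_conn,
                    "n_macro": rec.n_macro,
                }
            )
    return pd.DataFrame(rows)


def critical_beta(traces: list[OptimizationTrace], betas=None) -> float:
    """Beta below which re-selection degenerates to near-initial configs.

    The selected configurations' mean predictability as a function of
    beta forms two plateaus (low at small beta, high at large beta);
    the critical value is where the curve crosses the midpoint between
    them, located by linear interpolation on the beta grid.
    """
    if betas is None:
        betas = np.round(np.arange(0.01, 1.0, 0.02), 4)
    table = beta_sweep(traces, betas)
    curve = table.groupby("beta")["pred"].mean()
    b = curve.index.to_numpy()
    p = curve.to_numpy()
    mid = 0.5 * (p.max() + p.min())
    below = p < mid
    if not below.any():
        return float(b[0])
    if below.all():
        return float(b[-1])
    i = int(np.max(np.flatnonzero(below)))  # last beta under the midpoint
    if i + 1 >= len(b):
        return float(b[i])
    # linear interpolation of the crossing
    f = (mid - p[i]) / (p[i + 1] - p[i])
    return float(b[i] + f * (b[i + 1] - b[i]))


# ---------------------------------------------------------------------------
# Sensory-only collapse


def sensory_only_collapse(model: TransitionModel) -> TransitionModel:
    """Average the transition tensor over actions (motor identity lost).

    The collapsed model has a single 'action' whose rows are the
    unweighted mean of the per-action rows (random exploration draws
    actions uniformly), renormalized.
    """
    acc = model.tm[0].copy()
    for t in model.tm[1:]:
        acc = acc + t
    acc = sparse.csr_matrix(acc / model.n_actions)
    collapsed = normalize_counts([acc])
    collapsed.visit_counts = model.visit_counts.sum(axis=1, keepdims=True)
    return collapsed


def optimize_sensory_only(
    model: TransitionModel,
    settings: OptimizerSettings,
    rng: np.random.Generator,
) -> tuple[OptimizationTrace, dict]:
    """Optimize on the collapsed tensor, evaluate with the full tensor.

    The returned summary holds the full-tensor objective scores of the
    best configuration found on the collapsed tensor.
    """
    collapsed = sensory_only_collapse(model)
    trace = optimize(collapsed, settings, rng=rng)
    rep = evaluate(macro_transitions(trace.best_config, model), ObjectiveParams())
    return trace, rep.summary()


# ---------------------------------------------------------------------------
# Temporal stability


@dataclass(frozen=True)
class StabilityParams:
    """Motion-generator and scoring parameters for stability evaluation."""

    p_switch: float = 0.1  # probability of switching translation <-> rotation
    n_steps: int = 4000
    translation_step: float = 0.25  # step units per time step
    rotation_step_deg: float = 15.0


def config_to_place_fields(
    config: MacrostateConfig, grid: Grid, max_refine: int = 500
) -> tuple[np.ndarray, bool]:
    """Continuous activity fields (n_macro x M) recovering the partition.

    Each macrostate gets an isotropic Gaussian fitted to its largest
    connected component (centroid and RMS radius), then per-cell
    activities are refined multiplicatively until a winner-take-all
    operation over states reproduces the discrete configuration.  If
    refinement fails the fields fall back to indicator maps smoothed
    with a one-cell Gaussian (flagged through the second return value).
    """
    n, M = config.n_macro, config.n_micro
    fields = np.zeros((n, M))
    img = grid.label_image(config.labels, fill=-1)
    for s in range(n):
        comp, ncomp = ndimage.label(img == s)
        if ncomp > 1:
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, np.arange(1, ncomp + 1))
            keep = 1 + int(np.argmax(sizes))
            mask_img = comp == keep
        else:
            mask_img = comp > 0
        cells = np.flatnonzero(mask_img[grid.rowcol[:, 0], grid.rowcol[:, 1]])
        pts = grid.centers[cells]
        c = pts.mean(axis=0)
        sig = max(np.sqrt(((pts - c) ** 2).sum(axis=1).mean()), grid.cell_size)
        d2 = ((grid.centers - c) ** 2).sum(axis=1)
        fields[s] = np.exp(-d2 / (2 * sig**2))
    ok = False
    for _ in range(max_refine):
        winner = np.argmax(fields, axis=0)
        wrong = winner != config.labels
        if not wrong.any():
            ok = True
            break
        fields[config.labels[wrong], np.flatnonzero(wrong)] *= 1.05
    if not ok:
        # fallback: smoothed indicator fields (always WTA-consistent in
        # the interior; accepted as-is)
        for s in range(n):
            ind = (img == s).astype(float)
            fields[s] = ndimage.gaussian_filter(ind, sigma=1.0)[
                grid.rowcol[:, 0], grid.rowcol[:, 1]
            ]
    return fields, ok


def _motion_trajectory(
    maze: Maze, sp: StabilityParams, rng: np.random.Generator
) -> np.ndarray:
    """Translation/rotation random motion with obstacle avoidance."""
    pos = maze.sample_interior(rng)
    heading = rng.uniform(0, 2 * np.pi)
    mode = 0  # 0 translation, 1 rotation
    turn_dir = 1.0
    out = np.empty((sp.n_steps, 2))
    w = np.deg2rad(sp.rotation_step_deg)
    for t in range(sp.n_steps):
        if rng.random() < sp.p_switch:
            mode = 1 - mode
            if mode == 1:
                turn_dir = 1.0 if rng.random() < 0.5 else -1.0
        if mode == 1:
            heading += turn_dir * w
        else:
            step = sp.translation_step * np.array([np.cos(heading), np.sin(heading)])
            target = pos + step
            tries = 0
            while not maze.contains_point(target[0], target[1]) and tries < 24:
                heading += turn_dir * w  # avoid the wall by turning away
                step = sp.translation_step * np.array([np.cos(heading), np.sin(heading)])
                target = pos + step
                tries += 1
            if tries < 24:
                pos = target
        out[t] = pos
    return out


def _raw_instability(
    fields: np.ndarray, grid: Grid, traj: np.ndarray
) -> float:
    """Slowness of the population activity along a trajectory.

    Per state: mean squared one-step activity change divided by the
    activity variance (the classic slowness index, so amplitude scale
    cancels); averaged over states with nonzero variance.  Zero means
    perfectly stable (constant) activity.
    """
    cells = grid.cell_indices(traj)
    act = fields[:, cells]  # (n, T)
    tot = act.sum(axis=0)
    tot[tot == 0] = 1.0
    act = act / tot
    var = act.var(axis=1)
    msd = (np.diff(act, axis=1) ** 2).mean(axis=1)
    live = var > 1e-12
    if not live.any():
        return 0.0
    return float((msd[live] / var[live]).mean())


def stability_eval(
    config: MacrostateConfig,
    grid: Grid,
    maze: Maze,
    sp: StabilityParams = StabilityParams(),
    rng: np.random.Generator | None = None,
    reference: MacrostateConfig | None = None,
) -> float:
    """Temporal stability of a configuration's place-field activities.

    Zero denotes perfect stability; values are normalized so that a
    matched random configuration (same number of states, random labels)
    scores 1.  The same trajectory is used for both configurations.
    """
    if rng is None:
        rng = np.random.default_rng()
    traj = _motion_trajectory(maze, sp, rng)
    fields, _ = config_to_place_fields(config, grid)
    raw = _raw_instability(fields, grid, traj)
    if reference is None:
        reference = random_config(grid.n_cells, config.n_macro, rng)
    if reference is config:
        return 1.0 if raw > 0 else 0.0
    ref_fields, _ = config_to_place_fields(reference, grid)
    ref_raw = _raw_instability(ref_fields, grid, traj)
    if ref_raw == 0:
        return 0.0 if raw == 0 else np.inf
    return raw / ref_raw
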