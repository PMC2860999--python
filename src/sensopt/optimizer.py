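"""Rule-based cut/merge optimization of macrostate configurations.

The objective Psi is not differentiable in the space of partitions, so
the optimizer improves a configuration by two antagonistic local
operations guided by the objective's components:

* **cut** — a macrostate with below-median predictability is split in
  two by the normalized-cut graph partitioning algorithm applied to the
  projection-similarity graph of its member microstates (the uncentred
  correlation of their microstate-to-macrostate transition vectors,
  averaged over actions);
* **merge** — pairs of mutually correlated macrostates are combined,
  most correlated pairs first, skipping pairs whose merged state would
  have its self-connection as its largest transition probability.

Each iteration evaluates the current configuration, compiles candidate
lists, and applies merges when the mean decorrelation is below the mean
predictability, cuts otherwise.  A macrostate is modified at most once
per iteration.  An upper boundary on the number of macrostates —
cycling through 1000, 500 and 10 every 20 iterations — blocks cut
operations and prevents the process from oscillating into degenerate
configurations.  The result of a run is the configuration with the
highest mean Psi seen at any iteration, which need not be the final one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, sparse
from scipy.sparse import csgraph

from .macrostates import (
    MacrostateConfig,
    MacroTransitions,
    macro_transitions,
    membership_matrix,
    random_config,
)
from .microstates import TransitionModel
from .objective import ObjectiveParams, ObjectiveReport, evaluate

log = logging.getLogger(__name__)

__all__ = [
    "OptimizerSettings",
    "CandidateLists",
    "IterationRecord",
    "OptimizationTrace",
    "projection_vectors",
    "projection_similarity",
    "cut_state",
    "merge_states",
    "build_candidates",
    "step",
    "optimize",
]


@dataclass(frozen=True)
class OptimizerSettings:
    """Knobs of the cut/merge optimization loop."""

    max_iters: int = 3000
    boundary_schedule: tuple[int, ...] = (1000, 500, 10)
    boundary_period: int = 20
    beta: float = 0.8
    init_n_range: tuple[int, int] = (200, 800)
    max_leak: float = 0.01
    store_configs: bool = False

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if any(b < 1 for b in self.boundary_schedule):
            raise ValueError("boundary values must be >= 1")

    def boundary_at(self, iter_index: int) -> int:
        phase = (iter_index // self.boundary_period) % len(self.boundary_schedule)
        return self.boundary_schedule[phase]


@dataclass
class CandidateLists:
    """Disjoint merge pairs and cut candidates for one iteration."""

    merge_pairs: list[tuple[int, int]]
    cut_states: list[int]


# ---------------------------------------------------------------------------
# Projection similarity and normalized cut


def projection_vectors(model: TransitionModel, config: MacrostateConfig) -> list[sparse.csr_matrix]:
    """Per-action microstate-to-macrostate transition vectors (M x n)."""
    S = membership_matrix(config)
    return [sparse.csr_matrix(t @ S) for t in model.tm]


def _normalized_rows(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1)
    out = np.zeros_like(mat)
    nz = norms > 0
    out[nz] = mat[nz] / norms[nz, None]
    return out


def _similarity_graph(
    proj: list[sparse.csr_matrix], members: np.ndarray
) -> np.ndarray:
    """Dense projection-similarity matrix among the given microstates."""
    m = len(members)
    W = np.zeros((m, m))
    for P in proj:
        rows = _normalized_rows(P[members].toarray())
        W += rows @ rows.T
    W /= len(proj)
    return W


def projection_similarity(
    model: TransitionModel, config: MacrostateConfig, i: int, l: int
) -> float:
    """Uncentred correlation of two microstates' projection vectors.

    Averaged over actions; 1 for i == l, 0 if either microstate has an
    unsampled (zero) transition row for every action pairing considered.
    """
    if i == l:
        return 1.0
    proj = projection_vectors(model, config)
    W = _similarity_graph(proj, np.array([i, l]))
    return float(W[0, 1])


def _ncut_value(W: np.ndarray, mask: np.ndarray) -> float:
    """Normalized-cut objective of the bipartition given by ``mask``."""
    d = W.sum(axis=1)
    cut = W[np.ix_(mask, ~mask)].sum()
    a1 = d[mask].sum()
    a2 = d[~mask].sum()
    if a1 == 0 or a2 == 0:
        return np.inf
    return cut / a1 + cut / a2


def _spectral_bipartition(W: np.ndarray) -> np.ndarray:
    """Shi-Malik normalized cut: boolean mask of one side.

    Uses the second-smallest generalized eigenvector of (D - W, D) and
    scans every split of the sorted eigenvector, keeping the one with
    minimal Ncut.  A disconnected similarity graph is split along its
    connected components instead.
    """
    m = W.shape[0]
    n_comp, comp = csgraph.connected_components(sparse.csr_matrix(W > 0), directed=False)
    if n_comp > 1:
        # group whole components into two sides of balanced total size
        # (splitting off one tiny component at a time would shave the
        # state into a singleton spray over successive cuts)
        sizes = np.bincount(comp)
        order = np.argsort(sizes, kind="stable")[::-1]
        side = np.zeros(n_comp, dtype=bool)
        tot = np.array([0, 0])
        for c in order:
            pick = int(tot[1] < tot[0])
            side[c] = bool(pick)
            tot[pick] += sizes[c]
        return side[comp]
    d = W.sum(axis=1)
    L = np.diag(d) - W
    # d > 0 everywhere here (single connected component)
    vals, vecs = linalg.eigh(L, np.diag(d), subset_by_index=[1, 1])
    v = vecs[:, 0]
    order = np.argsort(v, kind="stable")
    Wo = W[np.ix_(order, order)]
    do = d[order]
    total = do.sum()
    cum_d = np.cumsum(do)
    best_k, best_val = None, np.inf
    wAA = 0.0
    for k in range(m - 1):
        wAA += 2.0 * Wo[k, :k].sum() + Wo[k, k]
        assocA = cum_d[k]
        assocB = total - assocA
        cut = assocA - wAA
        if assocA <= 0 or assocB <= 0:
            continue
        val = cut / assocA + cut / assocB
        if val < best_val - 1e-15:
            best_val, best_k = val, k
    if best_k is None:
        best_k = m // 2 - 1  # degenerate graph: balanced index split
    mask = np.zeros(m, dtype=bool)
    mask[order[: best_k + 1]] = True
    return mask


def cut_state(
    config: MacrostateConfig,
    model: TransitionModel,
    s: int,
    proj: list[sparse.csr_matrix] | None = None,
) -> MacrostateConfig:
    """Split macrostate ``s`` in two by normalized cut of its members."""
    members = config.members(s)
    if len(members) < 2:
        raise ValueError(f"macrostate {s} cannot be cut: fewer than 2 microstates")
    if proj is None:
        proj = projection_vectors(model, config)
    W = _similarity_graph(proj, members)
    mask = _spectral_bipartition(W)
    labels = config.labels.copy()
    labels[members[~mask]] = config.n_macro  # new label; stays dense
    return MacrostateConfig(labels=labels)


def merge_states(config: MacrostateConfig, a: int, b: int) -> MacrostateConfig:
    """Combine macrostates ``a`` and ``b`` into one; labels re-densified."""
    if a == b:
        raise ValueError("cannot merge a macrostate with itself")
    labels = config.labels.copy()
    labels[labels == b] = a
    return MacrostateConfig(labels=labels).relabeled()


# ---------------------------------------------------------------------------
# Candidate selection and the iteration rule


def _mean_rows(TM: MacroTransitions) -> np.ndarray:
    """(n, n) action-averaged transition matrix (dense)."""
    acc = TM.TM[0].copy()
    for t in TM.TM[1:]:
        acc = acc + t
    return np.asarray(acc.todense()) / TM.n_actions


def _merged_self_dominates(
    mean_rows: np.ndarray, sizes: np.ndarray, a: int, b: int
) -> bool:
    """Would the merged state's self-connection be its largest entry?"""
    na, nb = sizes[a], sizes[b]
    row = (na * mean_rows[a] + nb * mean_rows[b]) / (na + nb)
    self_p = row[a] + row[b]
    other = np.delete(row, [a, b])
    return self_p >= (other.max() if len(other) else 0.0)


def build_candidates(
    report: ObjectiveReport,
    TM: MacroTransitions,
    sizes: np.ndarray | None = None,
) -> CandidateLists:
    """Compile this iteration's merge pairs and cut candidates.

    Merge pairs are chosen greedily in ascending pairwise decorrelation
    (most correlated first, ties broken by state index), each state
    participating in at most one pair, discarding pairs whose merged
    state's action-averaged self-connection would be its largest
    action-averaged transition probability.  Pairs with decorrelation 1
    (orthogonal outcome distributions) are never rule-based merge
    candidates: combining them cannot improve either objective
    component.  Cut candidates are the states with predictability below
    the median.
    """
    n = TM.n_macro
    if sizes is None:
        sizes = np.ones(n)
    mean_rows = _mean_rows(TM)
    pair = report.decorr_pair
    iu, ju = np.triu_indices(n, k=1)
    vals = pair[iu, ju]
    # pairs with decorr == 1 (orthogonal transition rows) form one large
    # tie block at the end of the ranking; resolve it by index order
    # instead of materializing and sorting all n^2/2 pairs
    corr_idx = np.flatnonzero(vals < 1.0 - 1e-12)
    order = corr_idx[np.argsort(vals[corr_idx], kind="stable")]
    used = np.zeros(n, dtype=bool)
    merge_pairs: list[tuple[int, int]] = []
    for idx in order:
        a, b = int(iu[idx]), int(ju[idx])
        if used[a] or used[b]:
            continue
        if _merged_self_dominates(mean_rows, sizes, a, b):
            continue
        merge_pairs.append((a, b))
        used[a] = used[b] = True
    # cut score: predictability discounted by self-connectivity.  In the
    # intended operating regime (self-connectivity near zero) this equals
    # plain predictability; the discount matters only for states grown so
    # large that self-absorption inflates their row norm, which must not
    # shield them from being cut.
    diag = np.column_stack([t.diagonal() for t in TM.TM])
    score = report.pred * (1.0 - diag.mean(axis=1))
    med = np.median(score)
    cut_states = [int(s) for s in np.argsort(score, kind="stable") if score[s] < med]
    return CandidateLists(merge_pairs=merge_pairs, cut_states=cut_states)


def _ranked_pairs(pair: np.ndarray):
    """Disjoint macrostate pairs in ascending pairwise decorrelation.

    Same ranking as the merge-candidate list but without the
    self-connection veto; orthogonal states are paired in index order at
    the end.  Used when boundary compliance forces merges.
    """
    n = pair.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = pair[iu, ju]
    corr_idx = np.flatnonzero(vals < 1.0 - 1e-12)
    order = corr_idx[np.argsort(vals[corr_idx], kind="stable")]
    used = np.zeros(n, dtype=bool)
    out: list[tuple[int, int]] = []
    for idx in order:
        a, b = int(iu[idx]), int(ju[idx])
        if used[a] or used[b]:
            continue
        out.append((a, b))
        used[a] = used[b] = True
    leftovers = np.flatnonzero(~used)
    out.extend((int(a), int(b)) for a, b in zip(leftovers[::2], leftovers[1::2]))
    return out


@dataclass
class IterationRecord:
    """Summary of one optimizer iteration (evaluated before modification)."""

    iter_index: int
    n_macro: int
    mean_pred: float
    mean_decorr: float
    mean_self_conn: float
    mean_psi: float
    operation: str
    n_ops: int
    pred: np.ndarray = field(repr=False)
    decorr: np.ndarray = field(repr=False)
    self_conn: np.ndarray = field(repr=False)


@dataclass
class OptimizationTrace:
    """Per-iteration history plus the best configuration found."""

    records: list[IterationRecord]
    best_config: MacrostateConfig
    best_psi: float
    best_iter: int
    configs: list[MacrostateConfig] | None = None

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iter": [r.iter_index for r in self.records],
                "n_macro": [r.n_macro for r in self.records],
                "mean_pred": [r.mean_pred for r in self.records],
                "mean_decorr": [r.mean_decorr for r in self.records],
                "mean_self_conn": [r.mean_self_conn for r in self.records],
                "mean_psi": [r.mean_psi for r in self.records],
                "operation": [r.operation for r in self.records],
                "n_ops": [r.n_ops for r in self.records],
            }
        )

    def reselect(self, beta: float) -> tuple[int, IterationRecord]:
        """Best iteration when ranked by mean Psi recomputed with ``beta``.

        Uses the stored per-state components, so re-selection does not
        rerun any optimization.
        """
        means = [
            float(np.mean((beta * r.pred + (1 - beta) * r.decorr) * (1 - r.self_conn)))
            for r in self.records
        ]
        best = int(np.argmax(means))
        return best, self.records[best]


def step(
    config: MacrostateConfig,
    model: TransitionModel,
    settings: OptimizerSettings,
    iter_index: int,
) -> tuple[MacrostateConfig, IterationRecord]:
    """One optimizer iteration: evaluate, choose a branch, apply operations."""
    TM = macro_transitions(config, model, max_leak=settings.max_leak)
    report = evaluate(TM, ObjectiveParams(beta=settings.beta))
    cand = build_candidates(report, TM, sizes=config.sizes())
    boundary = settings.boundary_at(iter_index)
    n = config.n_macro
    new = config
    if n > boundary:
        # the boundary is an upper bound on the possible number of
        # macrostates: when the schedule drops below the current count,
        # the most correlated disjoint pairs are merged to comply
        # (at most n/2 per iteration; compliance may take a few)
        operation = "forced_merge"
        n_ops = 0
        labels = config.labels.copy()
        for a, b in _ranked_pairs(report.decorr_pair):
            if n - n_ops <= boundary:
                break
            labels[labels == b] = a
            n_ops += 1
        new = MacrostateConfig(labels=labels).relabeled()
    else:
        merge_wanted = report.decorr.mean() < report.pred.mean() and n > 1
        operation = "none"
        n_ops = 0
        if merge_wanted and cand.merge_pairs:
            operation = "merge"
            labels = config.labels.copy()
            for a, b in cand.merge_pairs:
                labels[labels == b] = a
                n_ops += 1
            new = MacrostateConfig(labels=labels).relabeled()
        else:
            # cut branch; also reached as a fallback when the merge
            # branch was selected but every candidate pair was vetoed
            # (an iteration must not silently idle in that case)
            if n < boundary:
                proj = projection_vectors(model, config)
                current = config
                for s in cand.cut_states:
                    if current.n_macro >= boundary:
                        break
                    if len(current.members(s)) < 2:
                        continue
                    current = cut_state(current, model, s, proj=proj)
                    n_ops += 1
                new = current
            if n_ops:
                operation = "cut"
    record = IterationRecord(
        iter_index=iter_index,
        n_macro=n,
        mean_pred=float(report.pred.mean()),
        mean_decorr=float(report.decorr.mean()),
        mean_self_conn=float(report.self_conn.mean()),
        mean_psi=report.mean_psi,
        operation=operation,
        n_ops=n_ops,
        pred=report.pred,
        decorr=report.decorr,
        self_conn=report.self_conn,
    )
    return new, record


def optimize(
    model: TransitionModel,
    settings: OptimizerSettings = OptimizerSettings(),
    rng: np.random.Generator | None = None,
    init_config: MacrostateConfig | None = None,
) -> OptimizationTrace:
    """Run the full cut/merge optimization from a random configuration."""
    if rng is None:
        rng = np.random.default_rng()
    if init_config is None:
        lo, hi = settings.init_n_range
        n0 = int(rng.integers(lo, hi + 1))
        n0 = min(n0, model.n_cells)
        init_config = random_config(model.n_cells, n0, rng)
    config = init_config
    records: list[IterationRecord] = []
    configs: list[MacrostateConfig] | None = [] if settings.store_configs else None
    best_psi = -np.inf
    best_config = config
    best_iter = 0
    for it in range(settings.max_iters):
        if configs is not None:
            configs.append(config)
        config_before = config
        config, rec = step(config, model, settings, it)
        records.append(rec)
        if rec.mean_psi > best_psi:
            best_psi = rec.mean_psi
            best_config = config_before
            best_iter = it
        if it % 50 == 0:
            log.info(
                "iter %d: n=%d pred=%.3f decorr=%.3f self=%.3f psi=%.3f op=%s x%d",
                it, rec.n_macro, rec.mean_pred, rec.mean_decorr,
                rec.mean_self_conn, rec.mean_psi, rec.operation, rec.n_ops,
            )
    return OptimizationTrace(
        records=records,
        best_config=best_config,
        best_psi=float(best_psi),
        best_iter=best_iter,
        configs=configs,
    )
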