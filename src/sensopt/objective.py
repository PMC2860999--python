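"""Scoring of macrostate configurations: predictability, decorrelation, Psi.

For a macrostate i, *predictability* is the sparseness of its transition
probability distributions, measured by the Euclidean norm and averaged
over actions:

    pred_i = (1/K) * sum_k || TM[i, :, k] ||_2

A one-hot row gives 1 (a fully deterministic transition); a uniform row
over n targets gives 1/sqrt(n).  *Decorrelation* between macrostates i
and j is one minus the uncentred correlation coefficient of their
transition distributions, averaged over actions (and taken at the
microstate level, so that partially overlapping outcome regions
register as similar); the per-state value decorr_i is the minimum over
all other states.  *Self-connectivity* is the
action-averaged probability of staying in the same macrostate.  The
objective of a macrostate combines the three:

    Psi_i = (beta * pred_i + (1 - beta) * decorr_i) * (1 - self_i)

so Psi lies in [0, 1] and attains 1 only at perfect predictability and
decorrelation with zero self-connectivity.  Configurations are ranked by
the unweighted mean of Psi over macrostates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .macrostates import MacroTransitions

__all__ = [
    "ObjectiveParams",
    "ObjectiveReport",
    "predictability",
    "decorrelation",
    "self_connectivity",
    "psi",
    "evaluate",
]


@dataclass(frozen=True)
class ObjectiveParams:
    """Weighting of predictability vs decorrelation; beta in (0, 1)."""

    beta: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie strictly between 0 and 1")


def _check_rows(TM: MacroTransitions, atol: float = 1e-6) -> None:
    for k, t in enumerate(TM.TM):
        sums = np.asarray(t.sum(axis=1)).ravel()
        if np.abs(sums - 1.0).max() > atol:
            raise ValueError(f"action {k}: transition rows are not normalized")


def _row_norms(TM: MacroTransitions) -> np.ndarray:
    """(n, K) Euclidean norms of the transition rows."""
    norms = np.empty((TM.n_macro, TM.n_actions))
    for k, t in enumerate(TM.TM):
        sq = t.copy()
        sq.data = sq.data**2
        norms[:, k] = np.sqrt(np.asarray(sq.sum(axis=1)).ravel())
    return norms


def predictability(TM: MacroTransitions, i: int | None = None):
    """Action-averaged Euclidean norm of transition rows (scalar or vector)."""
    _check_rows(TM)
    pred = _row_norms(TM).mean(axis=1)
    return pred if i is None else float(pred[i])


def _similarity(TM: MacroTransitions) -> sparse.csr_matrix:
    """Action-averaged uncentred correlation between transition distributions.

    For every action the source macrostates' transition distributions —
    the propagated microstate-occupancy distributions when available
    (the fine-grained view of where the action leads), the aggregated
    macrostate rows otherwise — are compared by the uncentred
    correlation coefficient, and the per-action correlations are
    averaged.  Absent entries of the returned sparse matrix are exact
    zeros (distributions orthogonal under every action).
    """
    mats = TM.micro_rows if TM.micro_rows is not None else TM.TM
    n = TM.n_macro
    sim = sparse.csr_matrix((n, n))
    for t in mats:
        sq = t.copy()
        sq.data = sq.data**2
        norms = np.sqrt(np.asarray(sq.sum(axis=1)).ravel())
        if (norms == 0).any():
            raise ValueError("zero-norm transition row")
        g = sparse.diags(1.0 / norms) @ t
        sim = sim + g @ g.T
    return sparse.csr_matrix(sim / len(mats))


def decorrelation(TM: MacroTransitions) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise decorrelation matrix and per-state minimum over others."""
    if TM.n_macro < 2:
        raise ValueError("decorrelation needs at least two macrostates")
    sim = _similarity(TM)
    pair = 1.0 - sim.toarray()
    np.fill_diagonal(pair, 0.0)
    off = sim.tolil()
    off.setdiag(0.0)
    off = off.tocsr()
    # per-row max of off-diagonal similarity; absent entries are 0
    max_sim = np.zeros(TM.n_macro)
    counts = np.diff(off.indptr)
    nz = counts > 0
    if nz.any():
        max_sim[nz] = np.maximum.reduceat(
            np.r_[off.data, -np.inf], off.indptr[:-1][nz]
        )
    max_sim = np.clip(max_sim, 0.0, None)
    return pair, 1.0 - max_sim


def self_connectivity(TM: MacroTransitions, i: int | None = None):
    """Action-averaged probability of remaining in the same macrostate."""
    diag = np.column_stack([t.diagonal() for t in TM.TM])
    sc = diag.mean(axis=1)
    return sc if i is None else float(sc[i])


def psi(pred, decorr, self_conn, params: ObjectiveParams = ObjectiveParams()):
    """Per-state objective (beta * pred + (1 - beta) * decorr) * (1 - self)."""
    b = params.beta
    return (b * np.asarray(pred) + (1 - b) * np.asarray(decorr)) * (
        1.0 - np.asarray(self_conn)
    )


@dataclass
class ObjectiveReport:
    """Per-macrostate scores of one configuration."""

    pred: np.ndarray
    decorr_pair: np.ndarray
    decorr: np.ndarray
    self_conn: np.ndarray
    psi: np.ndarray
    beta: float

    @property
    def mean_psi(self) -> float:
        return float(self.psi.mean())

    def summary(self) -> dict:
        return {
            "n_macro": len(self.pred),
            "mean_pred": float(self.pred.mean()),
            "mean_decorr": float(self.decorr.mean()),
            "mean_self_conn": float(self.self_conn.mean()),
            "mean_psi": self.mean_psi,
            "beta": self.beta,
        }


def evaluate(TM: MacroTransitions, params: ObjectiveParams = ObjectiveParams()) -> ObjectiveReport:
    """Score every macrostate of a configuration."""
    pred = predictability(TM)
    pair, decorr = decorrelation(TM)
    sc = self_connectivity(TM)
    return ObjectiveReport(
        pred=pred,
        decorr_pair=pair,
        decorr=decorr,
        self_conn=sc,
        psi=psi(pred, decorr, sc, params),
        beta=params.beta,
    )
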