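"""Macrostate configurations and action-conditioned macrostate transitions.

A macrostate configuration is a complete partition of the microstates
into disjoint macrostates, encoded as a dense integer label per
microstate.  Transition probabilities between macrostates are obtained
by activity propagation: probability mass of unit sum is injected
uniformly over the source macrostate's member microstates, propagated
one step along the per-action microstate transition graph, and summed
over each target macrostate's members.  This equals the aggregation
identity

    TM[i, j, k] = (1 / N_i) * sum_{a in i} sum_{b in j} tm[a, b, k]

with N_i the number of member microstates of macrostate i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .microstates import Grid, TransitionModel

__all__ = [
    "MacrostateConfig",
    "MacroTransitions",
    "init_activity",
    "propagate",
    "macro_transitions",
    "random_config",
    "membership_matrix",
]


@dataclass
class MacrostateConfig:
    """A partition of microstates into macrostates (dense labels 0..n-1)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_macro(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    @property
    def n_micro(self) -> int:
        return len(self.labels)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_macro)

    def members(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.labels == i)

    def validate(self) -> None:
        n = self.n_macro
        if self.labels.min() < 0:
            raise ValueError("negative macrostate label")
        if (self.sizes() == 0).any():
            raise ValueError("empty macrostate: labels are not dense")

    def relabeled(self) -> "MacrostateConfig":
        """Equivalent configuration with dense labels 0..n-1."""
        _, dense = np.unique(self.labels, return_inverse=True)
        return MacrostateConfig(labels=dense)


def membership_matrix(config: MacrostateConfig) -> sparse.csr_matrix:
    """Sparse (M x n_macro) indicator matrix S with S[a, i] = 1 iff cell a in macrostate i."""
    M = config.n_micro
    return sparse.csr_matrix(
        (np.ones(M), (np.arange(M), config.labels)), shape=(M, config.n_macro)
    )


def init_activity(config: MacrostateConfig, i: int) -> np.ndarray:
    """Unit probability mass spread uniformly over macrostate i's members."""
    members = config.members(i)
    if len(members) == 0:
        raise ValueError(f"macrostate {i} is empty")
    act = np.zeros(config.n_micro)
    act[members] = 1.0 / len(members)
    return act


def propagate(act: np.ndarray, model: TransitionModel, k: int) -> np.ndarray:
    """One propagation step of microstate occupancy under action k."""
    if not 0 <= k < model.n_actions:
        raise ValueError(f"action index {k} out of range")
    return np.asarray(act) @ model.tm[k]


@dataclass
class MacroTransitions:
    """Per-action macrostate transition matrices with leakage accounting.

    ``TM[k]`` is an ``n x n`` CSR matrix; ``leak[i, k]`` is the
    probability mass lost from (macrostate i, action k) through member
    microstate rows without samples, before renormalization.
    ``micro_rows[k]`` (``n x M``), when present, holds the propagated
    microstate-occupancy distribution of each source macrostate before
    aggregation onto target macrostates; decorrelation is measured on
    these fine-grained distributions.
    """

    TM: list[sparse.csr_matrix]
    leak: np.ndarray  # (n_macro, K)
    micro_rows: list[sparse.csr_matrix] | None = None

    @property
    def n_macro(self) -> int:
        return self.TM[0].shape[0]

    @property
    def n_actions(self) -> int:
        return len(self.TM)

    def dense(self) -> np.ndarray:
        """(n, n, K) dense array; convenient for small problems."""
        return np.dstack([t.toarray() for t in self.TM])


def macro_transitions(
    config: MacrostateConfig,
    model: TransitionModel,
    max_leak: float = 0.01,
) -> MacroTransitions:
    """Aggregate microstate transitions into macrostate transitions.

    Rows losing mass through unsampled microstate rows are renormalized
    provided the leak stays below ``max_leak``; a larger leak indicates
    insufficient exploration and raises with diagnostics.
    """
    if config.n_micro != model.n_cells:
        raise ValueError(
            f"configuration covers {config.n_micro} cells, tensor has {model.n_cells}"
        )
    S = membership_matrix(config)
    sizes = config.sizes().astype(float)
    inv = sparse.diags(1.0 / sizes)
    TM = []
    micro_rows = []
    leak = np.empty((config.n_macro, model.n_actions))
    for k in range(model.n_actions):
        prop = sparse.csr_matrix(inv @ (S.T @ model.tm[k]))  # injected + propagated
        t = sparse.csr_matrix(prop @ S)  # aggregated per target macrostate
        rowsum = np.asarray(t.sum(axis=1)).ravel()
        leak[:, k] = 1.0 - rowsum
        bad = leak[:, k] > max_leak
        if bad.any():
            worst = int(np.argmax(leak[:, k]))
            raise ValueError(
                f"action {k}: {int(bad.sum())} macrostate rows leak more than "
                f"{max_leak:.1%} of their mass (worst: macrostate {worst}, "
                f"leak {leak[worst, k]:.1%}); the transition tensor is "
                "insufficiently explored"
            )
        scale = np.divide(1.0, rowsum, out=np.ones_like(rowsum), where=rowsum > 0)
        t.data *= np.repeat(scale, np.diff(t.indptr))
        prop.data *= np.repeat(scale, np.diff(prop.indptr))
        TM.append(t)
        micro_rows.append(prop)
    return MacroTransitions(TM=TM, leak=leak, micro_rows=micro_rows)


def random_config(
    grid: Grid | int,
    n: int,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> MacrostateConfig:
    """Uniformly random macrostate label per microstate, all n nonempty."""
    M = grid if isinstance(grid, (int, np.integer)) else grid.n_cells
    if not 1 <= n <= M:
        raise ValueError(f"need 1 <= n <= {M}, got n={n}")
    for _ in range(max_retries):
        labels = rng.integers(0, n, size=M)
        if len(np.unique(labels)) == n:
            return MacrostateConfig(labels=labels)
    # extremely unlikely for n << M; force nonemptiness deterministically
    labels = rng.permutation(np.r_[np.arange(n), rng.integers(0, n, size=M - n)])
    return MacrostateConfig(labels=labels)
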