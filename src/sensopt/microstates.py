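"""Fine discretization of the arena and empirical transition sampling.

Microstates are the cells of a fine regular square lattice clipped to the
maze interior (a cell belongs to the grid when its centre lies inside the
maze).  The agent estimates, for every microstate i and action k, the
probability distribution over successor microstates by executing a single
long random walk (uniformly random actions, wall reflection) and counting
observed (source cell, action, target cell) triples.  Exploration stops
once a fraction ``coverage`` of the cells has been the source of at least
``min_visits`` actions.

The default cell size is one third of a step unit, i.e. one third of the
smallest canonical step length, which keeps the discretization fine
relative to every action primitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse

from .env_sim import Maze, MotorParams

__all__ = [
    "Grid",
    "TransitionModel",
    "build_grid",
    "explore",
    "normalize_counts",
    "restrict_to_sampled",
    "DEFAULT_CELL_SIZE",
]

DEFAULT_CELL_SIZE = 1 / 3


@dataclass
class Grid:
    """A regular lattice of microstates clipped to a maze interior.

    Cell ids are dense ``0..M-1``.  ``id_of[row, col]`` gives the id of a
    lattice position (-1 where the cell centre falls outside the maze);
    ``nearest_id`` maps every lattice position to the nearest valid cell
    so that interior points lying in a clipped border cell can still be
    binned.
    """

    cell_size: float
    x0: float
    y0: float
    nrows: int
    ncols: int
    rowcol: np.ndarray  # (M, 2) int
    centers: np.ndarray  # (M, 2) float
    id_of: np.ndarray  # (nrows, ncols) int
    nearest_id: np.ndarray  # (nrows, ncols) int

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    def cell_index(self, x: float, y: float) -> int:
        c = min(max(int((x - self.x0) / self.cell_size), 0), self.ncols - 1)
        r = min(max(int((y - self.y0) / self.cell_size), 0), self.nrows - 1)
        return int(self.nearest_id[r, c])

    def cell_indices(self, points: np.ndarray) -> np.ndarray:
        """Vectorized point-to-cell binning for an (N, 2) array."""
        pts = np.asarray(points, dtype=float)
        c = ((pts[:, 0] - self.x0) / self.cell_size).astype(np.intp).clip(0, self.ncols - 1)
        r = ((pts[:, 1] - self.y0) / self.cell_size).astype(np.intp).clip(0, self.nrows - 1)
        return self.nearest_id[r, c]

    def label_image(self, values: np.ndarray, fill=-1) -> np.ndarray:
        """Scatter a per-cell vector onto the (nrows, ncols) lattice."""
        img = np.full((self.nrows, self.ncols), fill, dtype=np.asarray(values).dtype)
        img[self.rowcol[:, 0], self.rowcol[:, 1]] = values
        return img

    def subset(self, keep: np.ndarray) -> "Grid":
        """A new grid containing only the cells where ``keep`` is True."""
        keep = np.asarray(keep, dtype=bool)
        if keep.all():
            return self
        old_ids = np.flatnonzero(keep)
        id_of = np.full_like(self.id_of, -1)
        id_of[self.rowcol[old_ids, 0], self.rowcol[old_ids, 1]] = np.arange(len(old_ids))
        nearest = _nearest_valid(id_of)
        return Grid(
            cell_size=self.cell_size,
            x0=self.x0,
            y0=self.y0,
            nrows=self.nrows,
            ncols=self.ncols,
            rowcol=self.rowcol[keep],
            centers=self.centers[keep],
            id_of=id_of,
            nearest_id=nearest,
        )


def _nearest_valid(id_of: np.ndarray) -> np.ndarray:
    valid = id_of >= 0
    if not valid.any():
        raise ValueError("grid has no valid cells")
    if valid.all():
        return id_of.copy()
    _, (ri, ci) = ndimage.distance_transform_edt(~valid, return_indices=True)
    return id_of[ri, ci]


def build_grid(maze: Maze, cell_size: float = DEFAULT_CELL_SIZE) -> Grid:
    """Lay a regular square lattice over the maze and keep interior cells."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    xmin, ymin, xmax, ymax = maze.bounds()
    if cell_size > min(xmax - xmin, ymax - ymin):
        raise ValueError("cell_size larger than the maze")
    ncols = int(np.ceil((xmax - xmin) / cell_size - 1e-9))
    nrows = int(np.ceil((ymax - ymin) / cell_size - 1e-9))
    if nrows < 1 or ncols < 1:
        raise ValueError("cell_size larger than the maze")
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    cx = xmin + (cc + 0.5) * cell_size
    cy = ymin + (rr + 0.5) * cell_size
    pts = np.column_stack([cx.ravel(), cy.ravel()])
    inside = maze.contains(pts).reshape(nrows, ncols)
    if not inside.any():
        raise ValueError("no cell centre lies inside the maze; cell_size too large")
    id_of = np.full((nrows, ncols), -1, dtype=np.int64)
    id_of[inside] = np.arange(int(inside.sum()))
    rowcol = np.column_stack(np.nonzero(inside)).astype(np.int64)
    centers = np.column_stack(
        [
            xmin + (rowcol[:, 1] + 0.5) * cell_size,
            ymin + (rowcol[:, 0] + 0.5) * cell_size,
        ]
    )
    return Grid(
        cell_size=float(cell_size),
        x0=float(xmin),
        y0=float(ymin),
        nrows=nrows,
        ncols=ncols,
        rowcol=rowcol,
        centers=centers,
        id_of=id_of,
        nearest_id=_nearest_valid(id_of),
    )


@dataclass
class TransitionModel:
    """Empirical per-action microstate transition probabilities.

    ``tm[k]`` is an ``M x M`` CSR matrix whose row i holds the probability
    distribution over successor cells after executing action k from cell
    i.  Rows with no recorded samples are all-zero and flagged through
    ``visit_counts``.
    """

    tm: list[sparse.csr_matrix]
    visit_counts: np.ndarray  # (M, K) number of times action k was taken from cell i

    @property
    def n_cells(self) -> int:
        return self.tm[0].shape[0]

    @property
    def n_actions(self) -> int:
        return len(self.tm)

    def unvisited_rows(self) -> np.ndarray:
        """Boolean (M, K) mask of (cell, action) rows with no samples."""
        return self.visit_counts == 0

    def check_row_stochastic(self, atol: float = 1e-9) -> None:
        for k, t in enumerate(self.tm):
            sums = np.asarray(t.sum(axis=1)).ravel()
            visited = self.visit_counts[:, k] > 0
            if not np.allclose(sums[visited], 1.0, atol=atol):
                raise ValueError(f"action {k}: visited rows do not sum to one")


def normalize_counts(counts) -> TransitionModel:
    """Turn raw transition counts into row-stochastic probabilities.

    ``counts`` may be a dense ``(M, M, K)`` integer array or a list of K
    sparse ``M x M`` matrices.  Each (source, action) row is divided by
    its sum; all-zero rows stay zero and are flagged as unvisited.
    """
    if isinstance(counts, np.ndarray):
        if counts.ndim != 3:
            raise ValueError("dense counts must be (M, M, K)")
        mats = [sparse.csr_matrix(counts[:, :, k]) for k in range(counts.shape[2])]
    else:
        mats = [sparse.csr_matrix(c) for c in counts]
    if any((m.data < 0).any() for m in mats):
        raise ValueError("negative counts")
    tm = []
    visits = np.zeros((mats[0].shape[0], len(mats)), dtype=np.int64)
    for k, m in enumerate(mats):
        rowsum = np.asarray(m.sum(axis=1)).ravel()
        visits[:, k] = rowsum
        scale = np.divide(1.0, rowsum, out=np.zeros_like(rowsum, dtype=float), where=rowsum > 0)
        t = sparse.csr_matrix(m, dtype=float)
        t.data *= np.repeat(scale, np.diff(t.indptr))
        tm.append(t)
    return TransitionModel(tm=tm, visit_counts=visits)


def restrict_to_sampled(model: TransitionModel, grid: Grid) -> tuple[TransitionModel, Grid]:
    """Drop cells lacking samples for some action and renormalize.

    After a finite exploration a few rarely occupied border cells may
    miss samples for one or more actions, which would leak probability
    mass during activity propagation.  Those cells are removed from the
    grid (positions binning into them map to the nearest kept cell) and
    the remaining rows are renormalized over the kept columns; the rare
    row whose observed successors were all dropped is completed with a
    stay-in-place self-loop.  The dropped fraction is small by
    construction (exploration already guarantees dense coverage).
    """
    keep = (model.visit_counts > 0).all(axis=1)
    if keep.all():
        return model, grid
    idx = np.flatnonzero(keep)
    tm = []
    for t in model.tm:
        t2 = sparse.csr_matrix(t[idx][:, idx])
        rowsum = np.asarray(t2.sum(axis=1)).ravel()
        # a row can lose every kept target when all its observed
        # successors were dropped; complete it with a stay-in-place
        # self-loop (local and mass conserving) instead of cascading
        # further drops
        empty = np.flatnonzero(rowsum == 0)
        if len(empty):
            t2 = t2.tolil()
            t2[empty, empty] = 1.0
            t2 = sparse.csr_matrix(t2)
            rowsum[empty] = 1.0
        scale = 1.0 / rowsum
        t2.data *= np.repeat(scale, np.diff(t2.indptr))
        tm.append(t2)
    model2 = TransitionModel(tm=tm, visit_counts=model.visit_counts[keep])
    return model2, grid.subset(keep)


def explore(
    maze: Maze,
    mp: MotorParams,
    grid: Grid,
    min_visits: int = 500,
    coverage: float = 0.95,
    rng: np.random.Generator | None = None,
    max_steps: int = 10**8,
) -> TransitionModel:
    """Estimate the transition tensor by one long uniform random walk.

    At every step the agent draws one of the eight actions uniformly at
    random and executes it (noise and wall reflection included).  A cell
    counts as visited each time an action is executed from it.  The walk
    stops when at least ``coverage`` of the cells have been visited
    ``min_visits`` times, or after ``max_steps`` as a hard safety cap.
    """
    if min_visits < 1:
        raise ValueError("min_visits must be >= 1")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    K = mp.n_actions
    M = grid.n_cells
    dirs = mp.directions()
    occ = np.zeros(M, dtype=np.int64)
    src_blocks: list[np.ndarray] = []
    act_blocks: list[np.ndarray] = []
    dst_blocks: list[np.ndarray] = []

    pos = maze.sample_interior(rng)
    cur_id = grid.cell_index(pos[0], pos[1])
    B = 8192
    steps = 0
    while steps < max_steps:
        B = min(B, max_steps - steps)
        acts = rng.integers(0, K, size=B)
        lengths = np.clip(rng.normal(mp.step_length, mp.sigma_sl, size=B), 0.0, None)
        thetas = dirs[acts] + np.deg2rad(rng.normal(0.0, mp.sigma_a_deg, size=B))
        disp = np.column_stack([lengths * np.cos(thetas), lengths * np.sin(thetas)])
        traj = np.empty((B, 2))
        i = 0
        while i < B:
            # speculative vectorized advance; fall back to scalar
            # reflection handling at the first wall contact
            chunk = min(256, B - i)
            cum = pos + np.cumsum(disp[i : i + chunk], axis=0)
            inside = maze.contains(cum)
            if inside.all():
                traj[i : i + chunk] = cum
                pos = cum[-1]
                i += chunk
            else:
                k = int(np.argmin(inside))
                if k:
                    traj[i : i + k] = cum[:k]
                    pos = cum[k - 1]
                from .env_sim import reflect_move

                pos = reflect_move(maze, pos, disp[i + k])
                traj[i + k] = pos
                i += k + 1
        dst = grid.cell_indices(traj)
        src = np.empty(B, dtype=dst.dtype)
        src[0] = cur_id
        src[1:] = dst[:-1]
        cur_id = int(dst[-1])
        src_blocks.append(src)
        act_blocks.append(acts)
        dst_blocks.append(dst)
        occ += np.bincount(src, minlength=M)
        steps += B
        if (occ >= min_visits).mean() >= coverage:
            break

    src = np.concatenate(src_blocks)
    act = np.concatenate(act_blocks)
    dst = np.concatenate(dst_blocks)
    counts = []
    for k in range(K):
        m = act == k
        counts.append(
            sparse.coo_matrix(
                (np.ones(int(m.sum())), (src[m], dst[m])), shape=(M, M)
            ).tocsr()
        )
    return normalize_counts(counts)
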