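"""Spatial structure of macrostates: area, solidity, roundness, similarity.

Because sensory space coincides with the arena, every macrostate
occupies a set of grid cells and can be analysed as a 2-D region.  Area
is the number of member microstates.  Solidity is area divided by the
area of the region's convex hull (computed on the pixelated cell set, so
it lies in (0, 1] with single-cell states at 1).  Eccentricity comes
from the ellipse with matching second central moments (ratio of focal
distance to major-axis length); roundness is 1 - eccentricity.  For
configuration-level summaries, solidity and roundness are additionally
weighted by the logarithm of the area so that singleton states (whose
solidity and roundness are trivially perfect) carry no weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .macrostates import MacrostateConfig
from .microstates import Grid

__all__ = [
    "RegionStats",
    "region_stats",
    "size_weighted",
    "config_similarity",
]


@dataclass
class RegionStats:
    """Per-macrostate region measures of one configuration."""

    area: np.ndarray
    solidity: np.ndarray
    eccentricity: np.ndarray

    @property
    def roundness(self) -> np.ndarray:
        return 1.0 - self.eccentricity

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "macrostate": np.arange(len(self.area)),
                "area": self.area,
                "solidity": self.solidity,
                "eccentricity": self.eccentricity,
                "roundness": self.roundness,
            }
        )


def region_stats(config: MacrostateConfig, grid: Grid) -> RegionStats:
    """Region measures for every macrostate of a configuration.

    A macrostate that is spatially disconnected is analysed as a single
    region (hull and moments over all its components together).
    """
    if config.n_micro != grid.n_cells:
        raise ValueError("configuration does not match the grid")
    img = grid.label_image(config.labels + 1, fill=0)
    n = config.n_macro
    area = np.zeros(n, dtype=np.int64)
    solidity = np.ones(n)
    ecc = np.zeros(n)
    for rp in regionprops(img):
        i = rp.label - 1
        area[i] = rp.area
        solidity[i] = rp.area / rp.area_convex
        ecc[i] = rp.eccentricity
    return RegionStats(area=area, solidity=solidity, eccentricity=ecc)


def size_weighted(stats: RegionStats) -> dict:
    """Configuration summary with log-area weighting.

    Each state's solidity/roundness is multiplied by ln(area), so
    singletons (ln 1 = 0) contribute nothing; the summary is the plain
    mean over macrostates of the weighted values.
    """
    w = np.log(stats.area.astype(float))
    return {
        "sw_solidity": float(np.mean(stats.solidity * w)),
        "sw_roundness": float(np.mean(stats.roundness * w)),
        "mean_solidity": float(stats.solidity.mean()),
        "mean_roundness": float(stats.roundness.mean()),
        "mean_area": float(stats.area.mean()),
    }


def _occupancy_correlation(a: MacrostateConfig, b: MacrostateConfig) -> np.ndarray:
    """Uncentred correlation of binary occupancy maps: |A∩B|/sqrt(|A||B|)."""
    na, nb = a.n_macro, b.n_macro
    overlap = np.zeros((na, nb))
    np.add.at(overlap, (a.labels, b.labels), 1.0)
    sa = a.sizes().astype(float)
    sb = b.sizes().astype(float)
    return overlap / np.sqrt(np.outer(sa, sb))


def config_similarity(
    a: MacrostateConfig, b: MacrostateConfig, matching: str = "greedy"
) -> float:
    """Topographical similarity of two configurations on the same grid.

    Every macrostate of the smaller configuration is associated with a
    spatially most-correlated macrostate of the other configuration;
    with ``matching="greedy"`` (default) the association is injective
    (assignments made in descending correlation order without
    replacement), with ``matching="best"`` each state independently
    takes its best match.  The result is the mean of the matched
    uncentred correlations, in [0, 1], and is symmetric in its
    arguments.
    """
    if a.n_micro != b.n_micro:
        raise ValueError("configurations live on different grids")
    C = _occupancy_correlation(a, b)
    if C.shape[0] > C.shape[1]:
        C = C.T
    if matching == "best":
        return float(C.max(axis=1).mean())
    if matching != "greedy":
        raise ValueError("matching must be 'greedy' or 'best'")
    if C.shape[0] == C.shape[1]:
        # equal-sized configurations: average both greedy orientations so
        # the measure is exactly symmetric even under tie-breaking
        return 0.5 * (_greedy_mean(C) + _greedy_mean(C.T))
    return _greedy_mean(C)


def _greedy_mean(C: np.ndarray) -> float:
    nsmall = C.shape[0]
    order = np.argsort(C, axis=None, kind="stable")[::-1]
    rows_done = np.zeros(C.shape[0], dtype=bool)
    cols_done = np.zeros(C.shape[1], dtype=bool)
    picked = []
    for flat in order:
        i, j = divmod(int(flat), C.shape[1])
        if rows_done[i] or cols_done[j]:
            continue
        picked.append(C[i, j])
        rows_done[i] = True
        cols_done[j] = True
        if len(picked) == nsmall:
            break
    return float(np.mean(picked))
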