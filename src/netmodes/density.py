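"""Rich-club edge classification, voxel edge-density maps, and map correlation.

High-degree "rich club" hub nodes anchor a structural core of the brain
network.  Each weighted edge is classified by its endpoints: rich-club (RC,
both endpoints rich), feeder (FC, exactly one), or local (LC, neither).
An edge-density map counts, per white-matter voxel, how many edges of a
chosen class pass through it (via consensus trajectory masks); density maps
are compared to eigenmode importance maps by Pearson correlation over a
white-matter mask, with a Fisher-z confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import Connectome, EdgeTrajectorySet, Grid, InvalidInputError

__all__ = [
    "EdgeClassMap",
    "DensityMap",
    "rich_club_nodes",
    "classify_edges",
    "edge_density_map",
    "correlate_maps",
]

EDGE_CLASSES = ("RC", "FC", "LC")


def rich_club_nodes(
    connectome: Connectome,
    degree_threshold: float | None = None,
    explicit: set[int] | list[int] | None = None,
    weighted: bool = False,
    top_fraction: float = 0.15,
) -> set[int]:
    """Identify rich-club (hub) node indices.

    Precedence: an ``explicit`` node set is returned verbatim (the primary
    pathway when hubs are known, e.g. planted by the synthetic generator);
    otherwise nodes with degree > ``degree_threshold`` (binary degree by
    default, weighted optional); otherwise the top ``top_fraction`` of nodes
    by degree.
    """
    if explicit is not None:
        rich = set(int(i) for i in explicit)
        if not rich <= set(range(connectome.n_nodes)):
            raise InvalidInputError("explicit rich set contains unknown node indices")
        return rich
    deg = (connectome.degrees() if weighted
           else (connectome.adjacency > 0).sum(axis=1).astype(float))
    if degree_threshold is not None:
        if degree_threshold < 0:
            raise InvalidInputError("degree threshold must be >= 0")
        rich = set(np.flatnonzero(deg > degree_threshold).tolist())
    else:
        k = max(1, int(round(top_fraction * connectome.n_nodes)))
        rich = set(np.argsort(-deg, kind="stable")[:k].tolist())
    if not rich:
        warnings.warn("empty rich-club set: every edge will be classified local")
    return rich


@dataclass
class EdgeClassMap:
    """RC/FC/LC category per weighted edge, plus the rich node set."""

    rich_nodes: set[int]
    table: pd.DataFrame     # columns i, j, weight, category

    def edges_in_class(self, category: str) -> list[tuple[int, int]]:
        sub = self.table[self.table["category"] == category]
        return [(int(r.i), int(r.j)) for r in sub.itertuples()]


def classify_edges(connectome: Connectome, rich: set[int]) -> EdgeClassMap:
    """Classify every nonzero edge as rich-club / feeder / local."""
    if not rich <= set(range(connectome.n_nodes)):
        raise InvalidInputError("rich set contains unknown node indices")
    iu, ju = np.triu_indices(connectome.n_nodes, k=1)
    w = connectome.adjacency[iu, ju]
    nz = w > 0
    rows = []
    for i, j, wt in zip(iu[nz], ju[nz], w[nz]):
        n_rich = (i in rich) + (j in rich)
        cat = {2: "RC", 1: "FC", 0: "LC"}[n_rich]
        rows.append({"i": int(i), "j": int(j), "weight": float(wt), "category": cat})
    return EdgeClassMap(rich_nodes=set(rich),
                        table=pd.DataFrame(rows, columns=["i", "j", "weight", "category"]))


@dataclass
class DensityMap:
    """Per-voxel count of edges whose consensus mask covers the voxel."""

    grid: Grid
    values: np.ndarray
    category: str = "all"


def edge_density_map(
    trajectories: EdgeTrajectorySet,
    edges: list[tuple[int, int]] | None = None,
    category: str = "all",
) -> DensityMap:
    """Count, per voxel, the edges (optionally a subset) passing through it."""
    values = np.zeros(trajectories.grid.shape, dtype=float)
    keys = (sorted(trajectories.consensus) if edges is None
            else [tuple(sorted(e)) for e in edges])
    for key in keys:
        mask = trajectories.consensus_for(*key)
        if len(mask):
            values[tuple(mask.T)] += 1
    return DensityMap(grid=trajectories.grid, values=values, category=category)


def correlate_maps(
    map_a: np.ndarray,
    map_b: np.ndarray,
    mask: np.ndarray,
) -> tuple[float, tuple[float, float]]:
    """Pearson r between two voxel maps over a mask, with Fisher-z 95% CI.

    ``map_a``/``map_b`` are volumes of identical shape (``ImportanceMap`` /
    ``DensityMap`` values arrays); ``mask`` is a boolean volume selecting the
    white-matter voxels entering the correlation.
    """
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    mask = np.asarray(mask, bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise InvalidInputError("maps and mask must share one grid shape")
    if not mask.any():
        raise InvalidInputError("empty white-matter mask")
    x, y = a[mask], b[mask]
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidInputError("correlation undefined: a map is constant on the mask")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if n <= 3 or abs(r) >= 1.0:
        return r, (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = scipy.stats.norm.ppf(0.975)
    return r, (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
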