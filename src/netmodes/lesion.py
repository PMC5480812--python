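"""Virtual spherical white-matter lesions and eigenmode importance maps.

A focal lesion is modelled as a sphere (default diameter 12 mm) placed at a
white-matter voxel.  Every edge whose consensus trajectory mask intersects
the sphere is weakened in proportion to the fraction of its mask volume
removed, further scaled by a "stoppage" parameter in (0, 1] expressing how
completely damaged tissue blocks streamlines:

    A_ij  ->  A_ij − stoppage · (voxels removed / total voxels) · A_ij

The *importance* of a voxel for a given eigenmode is the decrease in that
mode's eigenvalue when the lesion is centred there; the lesioned Laplacian
is fully re-eigendecomposed and the mode re-identified by inner-product
matching, since eigenvalue order can swap under perturbation.  Sweeping the
lesion centre over all white-matter voxels yields an importance map.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Connectome,
    DataInconsistencyError,
    EdgeTrajectorySet,
    Grid,
    InvalidInputError,
    build_laplacian,
    save_volume_nifti,
)
from .eigen import DEFAULT_MATCH_WINDOW, EigenSystem, eigendecompose, match_eigenmode

__all__ = [
    "Lesion",
    "ImportanceMap",
    "voxelize_sphere",
    "apply_lesion",
    "importance_at",
    "importance_map",
    "importance_maps",
    "stoppage_sweep",
]

DEFAULT_DIAMETER_MM = 12.0
DEFAULT_STOPPAGES = (0.25, 0.5, 0.75, 1.0)


class ConstantMapError(ValueError):
    """Correlation requested between maps at least one of which is constant."""


@dataclass(frozen=True)
class Lesion:
    """Spherical lesion: center (mm), diameter (mm), stoppage in (0, 1]."""

    center: tuple[float, float, float]
    diameter: float = DEFAULT_DIAMETER_MM
    stoppage: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if self.diameter <= 0:
            raise InvalidInputError("lesion diameter must be positive")
        if not 0 < self.stoppage <= 1:
            raise InvalidInputError("stoppage must be in (0, 1]")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def voxelize_sphere(lesion: Lesion, grid: Grid) -> np.ndarray:
    """All grid voxels whose centers lie within the lesion radius, (K, 3) int."""
    sp = np.asarray(grid.spacing)
    lo = grid.world_to_voxel(np.asarray(lesion.center) - lesion.radius - sp)
    hi = grid.world_to_voxel(np.asarray(lesion.center) + lesion.radius + sp)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(grid.shape) - 1)
    if np.any(lo > hi):
        warnings.warn("lesion sphere lies outside the grid; empty voxel set")
        return np.empty((0, 3), dtype=int)
    axes = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    idx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    world = grid.voxel_to_world(idx)
    inside = np.sum((world - np.asarray(lesion.center)) ** 2, axis=1) <= lesion.radius**2
    out = idx[inside]
    if len(out) == 0:
        warnings.warn("lesion sphere contains no voxel centers")
    return out


# --------------------------------------------------------------------------
# Precomputed edge geometry (flat arrays for fast sphere queries)
# --------------------------------------------------------------------------

class _EdgeGeometry:
    """Consensus-mask voxels of all weighted edges, flattened for vector ops."""

    def __init__(self, connectome: Connectome, trajectories: EdgeTrajectorySet):
        A = connectome.adjacency
        edges = []
        coords = []
        edge_of_voxel = []
        totals = []
        iu, ju = np.triu_indices(connectome.n_nodes, k=1)
        for i, j in zip(iu, ju):
            if A[i, j] <= 0:
                continue
            mask = trajectories.consensus_for(i, j)
            if len(mask) == 0:
                raise DataInconsistencyError(
                    f"edge ({i},{j}) has weight {A[i, j]:g} but an empty consensus mask"
                )
            eid = len(edges)
            edges.append((int(i), int(j)))
            coords.append(trajectories.grid.voxel_to_world(mask))
            edge_of_voxel.append(np.full(len(mask), eid, dtype=np.int32))
            totals.append(len(mask))
        self.edges = edges
        self.coords = np.vstack(coords) if coords else np.empty((0, 3))
        self.edge_of_voxel = (np.concatenate(edge_of_voxel) if edge_of_voxel
                              else np.empty(0, dtype=np.int32))
        self.totals = np.asarray(totals, dtype=float)

    def fractions(self, center: np.ndarray, radius: float) -> np.ndarray:
        """Per-edge fraction of consensus voxels inside the sphere."""
        if len(self.coords) == 0:
            return np.empty(0)
        d2 = np.sum((self.coords - center) ** 2, axis=1)
        inside = d2 <= radius**2
        removed = np.bincount(self.edge_of_voxel[inside], minlength=len(self.edges))
        return removed / self.totals


def _lesioned_adjacency(
    connectome: Connectome, geom: _EdgeGeometry, lesion: Lesion
) -> np.ndarray:
    f = geom.fractions(np.asarray(lesion.center), lesion.radius)
    A = connectome.adjacency.copy()
    hit = np.flatnonzero(f > 0)
    for e in hit:
        i, j = geom.edges[e]
        scale = 1.0 - lesion.stoppage * f[e]
        A[i, j] *= scale
        A[j, i] *= scale
    return A


def apply_lesion(
    connectome: Connectome,
    trajectories: EdgeTrajectorySet,
    lesion: Lesion,
) -> Connectome:
    """Weaken every edge traversing the lesion sphere.

    New weight = A_ij · (1 − stoppage · f) with f the fraction of the edge's
    consensus voxels inside the sphere.  Edges not intersecting the sphere
    are unchanged; symmetry is preserved.
    """
    geom = _EdgeGeometry(connectome, trajectories)
    return connectome.with_adjacency(_lesioned_adjacency(connectome, geom, lesion))


def importance_at(
    connectome: Connectome,
    trajectories: EdgeTrajectorySet,
    lesion: Lesion,
    reference: EigenSystem | None = None,
    mode: int = 2,
    window: int | None = DEFAULT_MATCH_WINDOW,
) -> float:
    """Eigenvalue decrease of one eigenmode under a single lesion.

    The reference eigensystem is that of the unlesioned connectome (computed
    here if not supplied).  Returns λ_ref − λ_matched; the value may be
    slightly negative in degenerate near-tie cases and is reported unclipped.
    If the lesion disconnects the graph a warning is emitted but the value is
    still returned.
    """
    if reference is None:
        reference = eigendecompose(build_laplacian(connectome))
    lesioned = apply_lesion(connectome, trajectories, lesion)
    sys = eigendecompose(build_laplacian(lesioned))
    if sys.n_zero_modes() > reference.n_zero_modes():
        warnings.warn("lesion disconnected the graph")
    m = match_eigenmode(reference.eigenvector(mode), mode, sys, window=window)
    return reference.eigenvalue(mode) - sys.eigenvalue(m.matched_index)


# --------------------------------------------------------------------------
# Importance maps
# --------------------------------------------------------------------------

@dataclass
class ImportanceMap:
    """Voxel map of eigenvalue decreases for one mode and stoppage setting.

    ``values`` is a dense volume on ``grid``; ``evaluated`` marks the
    lesion-centre voxels actually simulated (white-matter voxels at the
    chosen stride).  Voxels outside the white matter are exactly 0.
    """

    grid: Grid
    values: np.ndarray
    evaluated: np.ndarray   # bool volume
    mode: int
    stoppage: float
    diameter: float = DEFAULT_DIAMETER_MM

    def evaluated_values(self) -> np.ndarray:
        """Importance at the evaluated voxels (fixed voxel order)."""
        return self.values[self.evaluated]

    def to_nifti(self, path: str | Path) -> None:
        save_volume_nifti(self.values, self.grid, path)

    def to_tsv(self, path: str | Path) -> None:
        idx = np.argwhere(self.evaluated)
        pd.DataFrame({
            "vx": idx[:, 0], "vy": idx[:, 1], "vz": idx[:, 2],
            "value": self.values[self.evaluated],
        }).to_csv(path, sep="\t", index=False)


def _lesion_centers(
    trajectories: EdgeTrajectorySet, stride: int
) -> np.ndarray:
    """White-matter voxels (union of consensus masks), subsampled by stride."""
    if stride < 1:
        raise InvalidInputError("stride must be >= 1")
    wm = trajectories.white_matter_voxels()
    if len(wm) == 0:
        raise InvalidInputError("no consensus voxels: cannot build importance map")
    if stride > 1:
        wm = wm[np.all(wm % stride == 0, axis=1)]
    return wm


def importance_maps(
    connectome: Connectome,
    trajectories: EdgeTrajectorySet,
    modes: tuple[int, ...] = (2, 3, 4),
    stoppages: tuple[float, ...] = DEFAULT_STOPPAGES,
    stride: int = 1,
    diameter: float = DEFAULT_DIAMETER_MM,
    window: int | None = DEFAULT_MATCH_WINDOW,
) -> dict[tuple[int, float], ImportanceMap]:
    """Importance maps for several modes and stoppage settings in one sweep.

    The lesion geometry (per-edge removed fractions) is shared across modes
    and stoppages, so the cost is one eigendecomposition per lesion centre
    per stoppage.  Returns ``{(mode, stoppage): ImportanceMap}``.
    """
    geom = _EdgeGeometry(connectome, trajectories)
    reference = eigendecompose(build_laplacian(connectome))
    centers = _lesion_centers(trajectories, stride)
    grid = trajectories.grid
    radius = diameter / 2.0

    values = {ms: np.zeros(grid.shape) for ms in itertools.product(modes, stoppages)}
    evaluated = np.zeros(grid.shape, dtype=bool)
    evaluated[tuple(centers.T)] = True

    A0 = connectome.adjacency
    world_centers = grid.voxel_to_world(centers)
    for vox, center in zip(centers, world_centers):
        f = geom.fractions(center, radius)
        hit = np.flatnonzero(f > 0)
        if len(hit) == 0:
            continue
        hi, hj = np.array([geom.edges[e] for e in hit]).T
        for s in stoppages:
            A = A0.copy()
            scale = 1.0 - s * f[hit]
            A[hi, hj] *= scale
            A[hj, hi] *= scale
            sys = eigendecompose(build_laplacian(A))
            for mode in modes:
                m = match_eigenmode(reference.eigenvector(mode), mode, sys,
                                    window=window)
                values[(mode, s)][tuple(vox)] = (
                    reference.eigenvalue(mode) - sys.eigenvalue(m.matched_index)
                )
    return {
        (mode, s): ImportanceMap(grid=grid, values=values[(mode, s)],
                                 evaluated=evaluated, mode=mode, stoppage=s,
                                 diameter=diameter)
        for mode, s in itertools.product(modes, stoppages)
    }


def importance_map(
    connectome: Connectome,
    trajectories: EdgeTrajectorySet,
    mode: int = 2,
    stoppage: float = 1.0,
    stride: int = 1,
    diameter: float = DEFAULT_DIAMETER_MM,
    window: int | None = DEFAULT_MATCH_WINDOW,
) -> ImportanceMap:
    """Importance map for a single eigenmode and stoppage setting."""
    return importance_maps(connectome, trajectories, modes=(mode,),
                           stoppages=(stoppage,), stride=stride,
                           diameter=diameter, window=window)[(mode, stoppage)]


def stoppage_sweep(
    connectome: Connectome,
    trajectories: EdgeTrajectorySet,
    modes: tuple[int, ...] = (2, 3, 4),
    stoppages: tuple[float, ...] = DEFAULT_STOPPAGES,
    stride: int = 1,
    diameter: float = DEFAULT_DIAMETER_MM,
    window: int | None = DEFAULT_MATCH_WINDOW,
) -> pd.DataFrame:
    """Pairwise Pearson correlations of importance maps across stoppages.

    For each mode, every pair of stoppage settings is compared by the
    Pearson correlation of importance over the evaluated white-matter
    voxels.  Returns a tidy table (mode, stoppage_a, stoppage_b, r).
    """
    if len(stoppages) < 2:
        raise InvalidInputError("need at least two stoppage values")
    maps = importance_maps(connectome, trajectories, modes=modes,
                           stoppages=stoppages, stride=stride,
                           diameter=diameter, window=window)
    rows = []
    for mode in modes:
        for a, b in itertools.combinations(stoppages, 2):
            xa = maps[(mode, a)].evaluated_values()
            xb = maps[(mode, b)].evaluated_values()
            if a == b:
                r = 1.0
            else:
                if np.std(xa) == 0 or np.std(xb) == 0:
                    raise ConstantMapError(
                        f"importance map constant for mode {mode}; "
                        f"correlation undefined for stoppages {a}, {b}"
                    )
                r = float(np.corrcoef(xa, xb)[0, 1])
            rows.append({"mode": mode, "stoppage_a": a, "stoppage_b": b, "r": r})
    return pd.DataFrame(rows)
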