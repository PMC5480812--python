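"""Structural connectome containers, adjacency/Laplacian construction, and I/O.

A connectome is a weighted undirected graph whose nodes are gray-matter
regions (with hemisphere tag, centroid in mm, and region volume in voxels)
and whose edge weights are streamline densities from probabilistic
tractography.  The anatomical embedding of each edge is carried separately
as a set of white-matter voxels on a regular mm grid (the edge's
"trajectory"), from which a consensus mask is derived per edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Grid",
    "Connectome",
    "EdgeTrajectorySet",
    "LaplacianMatrix",
    "build_adjacency",
    "prune_nodes",
    "build_laplacian",
    "consensus_edge_mask",
    "read_connectome",
    "write_connectome",
    "read_trajectories",
    "write_trajectories",
]

# Relative tolerance for symmetry / row-sum / PSD checks (double precision
# eigensolves are accurate to ~1e-14; 1e-9 leaves headroom).
CHECK_RTOL = 1e-9


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateGraphError(ValueError):
    """Raised when an operation would leave fewer than two nodes."""


class DataInconsistencyError(ValueError):
    """Raised when connectome and trajectory data contradict each other."""


# --------------------------------------------------------------------------
# Voxel grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Regular voxel grid: world = origin + spacing * index (voxel centers).

    Parameters
    ----------
    origin : length-3, mm coordinate of the center of voxel (0, 0, 0).
    spacing : length-3 (or scalar), voxel edge length in mm.
    shape : length-3 voxel counts along x, y, z.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", tuple(float(v) for v in np.atleast_1d(self.origin)))
        sp = np.atleast_1d(self.spacing).astype(float)
        if sp.size == 1:
            sp = np.repeat(sp, 3)
        if np.any(sp <= 0):
            raise InvalidInputError("grid spacing must be positive")
        object.__setattr__(self, "spacing", tuple(float(v) for v in sp))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + np.asarray(self.spacing) * idx

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return np.rint((xyz - np.asarray(self.origin)) / np.asarray(self.spacing)).astype(int)

    def contains(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        shape = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < shape), axis=-1)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (NIfTI convention)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def to_dict(self) -> dict:
        return {"origin": list(self.origin), "spacing": list(self.spacing),
                "shape": list(self.shape)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Grid":
        return cls(tuple(d["origin"]), tuple(d["spacing"]), tuple(d["shape"]))


# --------------------------------------------------------------------------
# Connectome
# --------------------------------------------------------------------------

@dataclass
class Connectome:
    """Weighted undirected structural brain network with node metadata.

    ``adjacency[i, j]`` is the streamline density A_ij between regions i and
    j (symmetric, non-negative, zero diagonal).  ``volumes`` are region
    volumes V_i in voxels, used when building A from streamline counts.
    """

    node_ids: list[str]
    hemisphere: np.ndarray          # per node, "L" or "R"
    centroids: np.ndarray           # (N, 3) mm
    volumes: np.ndarray             # (N,) voxels, > 0
    adjacency: np.ndarray           # (N, N)

    def __post_init__(self):
        self.node_ids = list(self.node_ids)
        self.hemisphere = np.asarray(self.hemisphere)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=float)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def validate(self) -> None:
        n = self.n_nodes
        A = self.adjacency
        if A.shape != (n, n):
            raise InvalidInputError("adjacency shape does not match node count")
        for name, arr in (("hemisphere", self.hemisphere),
                          ("centroids", self.centroids),
                          ("volumes", self.volumes)):
            if len(arr) != n:
                raise InvalidInputError(f"{name} length does not match node count")
        scale = max(np.abs(A).max(), 1.0)
        if not np.allclose(A, A.T, atol=CHECK_RTOL * scale):
            raise InvalidInputError("adjacency must be symmetric")
        if np.any(A < 0):
            raise InvalidInputError("adjacency must be entrywise non-negative")
        if np.any(np.abs(np.diag(A)) > CHECK_RTOL * scale):
            raise InvalidInputError("adjacency diagonal must be zero")
        if np.any(self.volumes <= 0):
            raise InvalidInputError("region volumes must be positive")

    def degrees(self) -> np.ndarray:
        """Weighted node degrees (row sums of A)."""
        return self.adjacency.sum(axis=1)

    def with_adjacency(self, adjacency: np.ndarray) -> "Connectome":
        """Copy of this connectome with a new adjacency (metadata shared)."""
        return replace(self, adjacency=np.asarray(adjacency, dtype=float))

    def hemisphere_mask(self, side: str) -> np.ndarray:
        return self.hemisphere == side


@dataclass
class LaplacianMatrix:
    """Graph Laplacian L = D − A of a connectome (symmetric PSD)."""

    matrix: np.ndarray
    connectome: Connectome | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)


# --------------------------------------------------------------------------
# Edge trajectories / consensus masks
# --------------------------------------------------------------------------

def _key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass
class EdgeTrajectorySet:
    """Per-edge white-matter voxel sets on a shared grid.

    ``directed[(i, j)]`` maps an ordered node pair to ``(voxels, counts)``
    where voxels is an (M, 3) int index array and counts the per-voxel
    streamline counts.  ``consensus[(i, j)] (i < j)`` is the union of the
    top-ranked non-zero voxels of the two directions (see
    :func:`consensus_edge_mask`).
    """

    grid: Grid
    directed: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]
    consensus: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def build_consensus(self, retain_fraction: float = 0.95) -> None:
        """(Re)compute every edge's consensus mask from the directed sets."""
        pairs = {_key(i, j) for (i, j) in self.directed}
        self.consensus = {}
        for (i, j) in sorted(pairs):
            fwd = self.directed.get((i, j), (np.empty((0, 3), int), np.empty(0)))
            rev = self.directed.get((j, i), (np.empty((0, 3), int), np.empty(0)))
            self.consensus[(i, j)] = consensus_edge_mask(
                fwd[0], fwd[1], rev[0], rev[1], retain_fraction=retain_fraction
            )

    def consensus_for(self, i: int, j: int) -> np.ndarray:
        return self.consensus.get(_key(i, j), np.empty((0, 3), dtype=int))

    def white_matter_voxels(self) -> np.ndarray:
        """Unique union of all consensus-mask voxels, (V, 3) int."""
        masks = [m for m in self.consensus.values() if len(m)]
        if not masks:
            return np.empty((0, 3), dtype=int)
        return np.unique(np.vstack(masks), axis=0)

    def validate(self, connectome: Connectome | None = None) -> None:
        for (i, j), mask in self.consensus.items():
            fwd = self.directed.get((i, j), (np.empty((0, 3), int),))[0]
            rev = self.directed.get((j, i), (np.empty((0, 3), int),))[0]
            union = {tuple(v) for v in fwd} | {tuple(v) for v in rev}
            if not {tuple(v) for v in mask} <= union:
                raise DataInconsistencyError(
                    f"consensus mask of edge ({i},{j}) not within directed voxel union"
                )
        if connectome is not None:
            nz = np.argwhere(np.triu(connectome.adjacency, 1) > 0)
            for i, j in nz:
                if len(self.consensus_for(i, j)) == 0:
                    raise DataInconsistencyError(
                        f"edge ({i},{j}) has positive weight but empty consensus mask"
                    )


def consensus_edge_mask(
    voxels_ij: np.ndarray,
    counts_ij: np.ndarray,
    voxels_ji: np.ndarray,
    counts_ji: np.ndarray,
    retain_fraction: float = 0.95,
) -> np.ndarray:
    """Consensus white-matter mask of one edge from its two tracking directions.

    For each direction independently, the non-zero voxels are ranked by
    streamline count and the top ``retain_fraction`` of them (ceil rounding;
    the weakest 5% by rank are dropped at the default) are retained.  The
    consensus mask is the union of the two retained sets.

    Ranking ties are broken by lexicographic voxel index so the result is
    deterministic.
    """
    if not 0 < retain_fraction <= 1:
        raise InvalidInputError("retain_fraction must be in (0, 1]")

    def _top(voxels, counts):
        voxels = np.asarray(voxels, dtype=int).reshape(-1, 3)
        counts = np.asarray(counts, dtype=float).reshape(-1)
        nz = counts > 0
        voxels, counts = voxels[nz], counts[nz]
        if len(voxels) == 0:
            return voxels
        keep = int(np.ceil(retain_fraction * len(voxels)))
        # sort by count desc, ties by voxel index for determinism
        order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0], -counts))
        return voxels[order[:keep]]

    top_fwd = _top(voxels_ij, counts_ij)
    top_rev = _top(voxels_ji, counts_ji)
    if len(top_fwd) == 0 and len(top_rev) == 0:
        import warnings

        warnings.warn("both directions empty; returning empty consensus mask")
        return np.empty((0, 3), dtype=int)
    return np.unique(np.vstack([top_fwd.reshape(-1, 3), top_rev.reshape(-1, 3)]), axis=0)


# --------------------------------------------------------------------------
# Adjacency and Laplacian construction
# --------------------------------------------------------------------------

def build_adjacency(streamlines: np.ndarray, volumes: np.ndarray) -> np.ndarray:
    """Volume-normalised, direction-averaged adjacency from streamline counts.

    Each directed count S_ij is normalised by the summed source and target
    region volumes, A_ij = S_ij / (V_i + V_j), and the two directions are
    averaged, giving A_ij = (S_ij + S_ji) / (2 (V_i + V_j)).  The
    normalisation prevents large regions from dominating simply by seeding
    or receiving more streamlines.
    """
    S = np.asarray(streamlines, dtype=float)
    V = np.asarray(volumes, dtype=float)
    if np.any(S < 0):
        raise InvalidInputError("streamline counts must be non-negative")
    if np.any(V <= 0):
        raise InvalidInputError("region volumes must be positive")
    if S.shape[0] != S.shape[1] or S.shape[0] != len(V):
        raise InvalidInputError("streamline matrix / volume length mismatch")
    denom = V[:, None] + V[None, :]
    A = (S + S.T) / (2.0 * denom)
    np.fill_diagonal(A, 0.0)
    return A


def prune_nodes(
    connectome: Connectome,
    explicit_exclusions: Sequence[str] = (),
    min_degree: float = 0.0,
) -> tuple[Connectome, list[str]]:
    """Remove named nodes and nodes with weighted degree <= ``min_degree``.

    Near-isolated nodes dominate the slow Laplacian eigenmodes without being
    physiologically meaningful, so they are pruned before analysis.  Returns
    the pruned connectome and the list of removed node ids.  Idempotent.
    """
    unknown = set(explicit_exclusions) - set(connectome.node_ids)
    if unknown:
        raise InvalidInputError(f"exclusion labels not in connectome: {sorted(unknown)}")
    if min_degree < 0:
        raise InvalidInputError("min_degree must be >= 0")

    keep = np.ones(connectome.n_nodes, dtype=bool)
    removed: list[str] = []
    for idx, nid in enumerate(connectome.node_ids):
        if nid in explicit_exclusions:
            keep[idx] = False
            removed.append(nid)
    # degree computed on the subgraph after explicit exclusions, iterated to
    # a fixed point so removals cannot strand new low-degree nodes
    while True:
        sub = connectome.adjacency[np.ix_(keep, keep)]
        deg = sub.sum(axis=1)
        low = deg <= min_degree if min_degree > 0 else deg <= 0
        if not low.any():
            break
        kept_idx = np.flatnonzero(keep)
        for local in np.flatnonzero(low):
            keep[kept_idx[local]] = False
            removed.append(connectome.node_ids[kept_idx[local]])

    if keep.sum() < 2:
        raise DegenerateGraphError("pruning left fewer than 2 nodes")
    idx = np.flatnonzero(keep)
    pruned = Connectome(
        node_ids=[connectome.node_ids[k] for k in idx],
        hemisphere=connectome.hemisphere[idx],
        centroids=connectome.centroids[idx],
        volumes=connectome.volumes[idx],
        adjacency=connectome.adjacency[np.ix_(idx, idx)],
    )
    return pruned, removed


def build_laplacian(connectome: Connectome | np.ndarray) -> LaplacianMatrix:
    """Graph Laplacian L = D − A (D = diagonal of weighted degrees).

    L is symmetric positive semidefinite with zero row sums; the network
    diffusion model dx/dt = −βLx is linear in L, and its eigenmodes are the
    objects of study throughout this package.
    """
    if isinstance(connectome, Connectome):
        A = connectome.adjacency
        source = connectome
    else:
        A = np.asarray(connectome, dtype=float)
        source = None
    scale = max(np.abs(A).max(), 1.0) if A.size else 1.0
    if not np.allclose(A, A.T, atol=CHECK_RTOL * scale):
        raise InvalidInputError("adjacency must be symmetric")
    L = np.diag(A.sum(axis=1)) - A
    np.fill_diagonal(L, A.sum(axis=0))  # use column sums == row sums; keeps exact symmetry
    L = (L + L.T) / 2.0
    return LaplacianMatrix(matrix=L, connectome=source)


# --------------------------------------------------------------------------
# I/O: TSV adjacency + metadata, sparse trajectory table, grid sidecar
# --------------------------------------------------------------------------

def write_connectome(connectome: Connectome, prefix: str | Path) -> None:
    """Write ``<prefix>_adjacency.tsv`` and ``<prefix>_nodes.tsv``."""
    prefix = Path(prefix)
    adj = pd.DataFrame(connectome.adjacency, index=connectome.node_ids,
                       columns=connectome.node_ids)
    adj.to_csv(prefix.with_name(prefix.name + "_adjacency.tsv"), sep="\t")
    meta = pd.DataFrame({
        "node_id": connectome.node_ids,
        "hemisphere": connectome.hemisphere,
        "x_mm": connectome.centroids[:, 0],
        "y_mm": connectome.centroids[:, 1],
        "z_mm": connectome.centroids[:, 2],
        "volume_voxels": connectome.volumes,
    })
    meta.to_csv(prefix.with_name(prefix.name + "_nodes.tsv"), sep="\t", index=False)


def read_connectome(prefix: str | Path) -> Connectome:
    prefix = Path(prefix)
    adj = pd.read_csv(prefix.with_name(prefix.name + "_adjacency.tsv"),
                      sep="\t", index_col=0)
    meta = pd.read_csv(prefix.with_name(prefix.name + "_nodes.tsv"), sep="\t")
    meta = meta.set_index("node_id").loc[adj.index]
    return Connectome(
        node_ids=list(adj.index.astype(str)),
        hemisphere=meta["hemisphere"].to_numpy(),
        centroids=meta[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        volumes=meta["volume_voxels"].to_numpy(float),
        adjacency=adj.to_numpy(float),
    )


def write_trajectories(traj: EdgeTrajectorySet, prefix: str | Path) -> None:
    """Write ``<prefix>_trajectories.tsv`` (i, j, vx, vy, vz, count) and a
    YAML grid sidecar ``<prefix>_grid.yaml``."""
    prefix = Path(prefix)
    rows = []
    for (i, j), (vox, cnt) in sorted(traj.directed.items()):
        for v, c in zip(vox, cnt):
            rows.append((i, j, int(v[0]), int(v[1]), int(v[2]), float(c)))
    pd.DataFrame(rows, columns=["i", "j", "vx", "vy", "vz", "count"]).to_csv(
        prefix.with_name(prefix.name + "_trajectories.tsv"), sep="\t", index=False
    )
    with open(prefix.with_name(prefix.name + "_grid.yaml"), "w") as fh:
        yaml.safe_dump(traj.grid.to_dict(), fh)


def read_trajectories(prefix: str | Path, retain_fraction: float = 0.95) -> EdgeTrajectorySet:
    prefix = Path(prefix)
    tab = pd.read_csv(prefix.with_name(prefix.name + "_trajectories.tsv"), sep="\t")
    with open(prefix.with_name(prefix.name + "_grid.yaml")) as fh:
        grid = Grid.from_dict(yaml.safe_load(fh))
    directed: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for (i, j), sub in tab.groupby(["i", "j"]):
        directed[(int(i), int(j))] = (
            sub[["vx", "vy", "vz"]].to_numpy(int),
            sub["count"].to_numpy(float),
        )
    out = EdgeTrajectorySet(grid=grid, directed=directed)
    out.build_consensus(retain_fraction=retain_fraction)
    return out


def save_volume_nifti(values: np.ndarray, grid: Grid, path: str | Path) -> None:
    """Write a scalar voxel volume on ``grid`` as NIfTI."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid.affine)
    nib.save(img, str(path))
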