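"""Synthetic two-hemisphere connectomes with anatomically embedded edges.

The generator emulates the statistical structure the analyses assume, so
every stage of the package is testable without imaging data:

* ~80 regions split evenly across two hemispheres, mirrored in x about the
  midsagittal plane x = 0, with positive region volumes;
* directed streamline counts whose expectation decays exponentially with
  inter-centroid distance and is boosted between planted hub (rich-club)
  nodes; homotopic (mirror-pair) regions are always connected;
* edge trajectories as discretized straight or single-bend polylines between
  centroids on a regular mm grid; every callosally routed interhemispheric
  trajectory passes through midline (x = 0) voxels, while "detour" routes
  avoid the midline column entirely (the stand-in for non-callosal
  commissural paths in callosal agenesis);
* paired scans per subject with multiplicative log-normal weight noise for
  test–retest analyses (additive noise would break non-negativity of
  streamline densities).

None of this reproduces diffusion-MRI physics or real anatomy; it produces
graphs and voxel geometries with the right invariants and qualitative
structure (distance decay, hemispheric organisation, hubs, callosal
bottleneck).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.csgraph

from .core import (
    Connectome,
    EdgeTrajectorySet,
    Grid,
    InvalidInputError,
    build_adjacency,
)

__all__ = [
    "GeneratorParams",
    "Subject",
    "CohortTable",
    "generate_connectome",
    "generate_cohort",
    "generate_agcc_variant",
    "toy_atlas",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic connectome generator.

    Defaults give an 80-node, two-hemisphere network on a 64³ grid at 2 mm
    spacing with ~25–35% connection density, 8 planted hubs, all
    interhemispheric edges routed through the midline, and 10% multiplicative
    scan noise.
    """

    n_nodes: int = 80
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 2.0
    decay_length_mm: float = 30.0      # e-folding length of count decay
    connect_scale: float = 1.5         # distance-zero connection probability
    base_count: float = 400.0          # expected streamline count at d = 0
    n_hubs: int = 8                    # planted rich-club nodes (mirrored pairs)
    hub_multiplier: float = 3.0        # count boost between two hubs
    inter_attenuation: float = 0.2     # interhemispheric count/probability factor
    callosal_fraction: float = 1.0     # interhemispheric edges routed via midline
    scan_noise_sd: float = 0.1         # log-normal sigma of scan noise
    subject_weight_sd: float = 0.2     # log-normal sigma of subject edge effects
    volume_mean: float = 100.0         # voxels; log-normal sigma 0.3
    # minimum inter-centroid distance: regions of ~volume_mean voxels at 2 mm
    # (~800 mm^3, equivalent-sphere diameter ~11.5 mm) cannot overlap, so
    # centroids of distinct regions are at least one region diameter apart
    min_node_distance_mm: float = 12.0
    retain_fraction: float = 0.95      # consensus-mask voxel retention
    # tract bundle radius: trajectories are tubes around the polyline route,
    # so an edge's mask volume is large compared to what one 12 mm lesion
    # removes — the small-perturbation regime the importance method assumes
    tract_radius_mm: float = 4.0
    max_retries: int = 10

    def __post_init__(self):
        if self.n_nodes < 4 or self.n_nodes % 2:
            raise InvalidInputError("n_nodes must be an even number >= 4")
        for name in ("spacing_mm", "decay_length_mm", "connect_scale",
                     "base_count", "hub_multiplier", "volume_mean"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if not 0 < self.inter_attenuation <= 1:
            raise InvalidInputError("inter_attenuation must be in (0, 1]")
        if not 0 <= self.callosal_fraction <= 1:
            raise InvalidInputError("callosal_fraction must be in [0, 1]")
        if self.scan_noise_sd < 0 or self.subject_weight_sd < 0:
            raise InvalidInputError("noise standard deviations must be >= 0")

    def make_grid(self) -> Grid:
        """Grid centred so a voxel-center column lies exactly on x = 0."""
        shape = tuple(self.grid_shape)
        origin = tuple(-(s // 2) * self.spacing_mm for s in shape)
        return Grid(origin=origin, spacing=(self.spacing_mm,) * 3, shape=shape)


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)  # accepts int, None, or SeedSequence


def _place_nodes(params: GeneratorParams, rng: np.random.Generator):
    """Mirror-symmetric centroids; right hemisphere = left with x negated.

    Dart-throwing enforces the minimum inter-centroid distance within a
    hemisphere (across hemispheres the x-band gap of >= 20 mm suffices).
    """
    half = params.n_nodes // 2
    grid = params.make_grid()
    extent = np.asarray(grid.spacing) * (np.asarray(grid.shape) - 1) / 2.0
    # brain-like proportions: anterior-posterior (y) > superior-inferior (z)
    # > per-hemisphere medial-lateral (x) extent; the anisotropy separates
    # the slow intrahemispheric gradient modes as in real connectomes
    lo = np.array([10.0, -0.88 * extent[1], -0.56 * extent[2]])
    hi = np.array([0.76 * extent[0], 0.88 * extent[1], 0.56 * extent[2]])
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < half:
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - p) >= params.min_node_distance_mm for p in pts):
            pts.append(cand)
        attempts += 1
        if attempts > 10000 * half:
            raise RuntimeError("node placement failed: min_node_distance too large")
    placed = np.array(pts)
    left = placed * np.array([-1.0, 1.0, 1.0])
    right = placed
    centroids = np.vstack([left, right])
    hemis = np.array(["L"] * half + ["R"] * half)
    ids = [f"L{k:02d}" for k in range(half)] + [f"R{k:02d}" for k in range(half)]
    return ids, hemis, centroids


def _polyline_voxels(points_mm: np.ndarray, grid: Grid) -> np.ndarray:
    """Discretize a polyline (list of mm waypoints) to unique grid voxels."""
    step = min(grid.spacing) / 2.0
    samples = []
    for a, b in zip(points_mm[:-1], points_mm[1:]):
        a, b = np.asarray(a, float), np.asarray(b, float)
        n = max(int(np.ceil(np.linalg.norm(b - a) / step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)
        samples.append(a + t[:, None] * (b - a))
    pts = np.vstack(samples)
    vox = grid.world_to_voxel(pts)
    vox = vox[grid.contains(vox)]
    if len(vox) == 0:
        return np.empty((0, 3), dtype=int)
    _, first = np.unique(vox, axis=0, return_index=True)
    return vox[np.sort(first)]


def _ball_offsets(radius_mm: float, grid: Grid) -> np.ndarray:
    """Integer voxel offsets within radius_mm of the origin (tube kernel)."""
    r_vox = np.floor(radius_mm / np.asarray(grid.spacing)).astype(int)
    ax = [np.arange(-r, r + 1) for r in r_vox]
    off = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    mm = off * np.asarray(grid.spacing)
    return off[np.sum(mm**2, axis=1) <= radius_mm**2]


def _dilate(vox: np.ndarray, offsets: np.ndarray, grid: Grid) -> np.ndarray:
    """Dilate a voxel path by a ball kernel (unique, clipped to grid)."""
    if len(vox) == 0:
        return vox
    fat = (vox[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    fat = fat[grid.contains(fat)]
    return np.unique(fat, axis=0)


def _edge_route(
    ci: np.ndarray, cj: np.ndarray, grid: Grid, route: str,
    radius_mm: float = 0.0, jitter: float = 0.0
) -> np.ndarray:
    """Voxel tube between two centroids.

    ``route``: "straight" for intra-hemispheric edges; "callosal" bends
    superiorly through a midline waypoint (guaranteeing x = 0 voxels);
    "detour" bends inferiorly and drops every midline-column voxel — also
    after dilation — emulating a non-callosal commissural path.  The path is
    dilated to a tube of ``radius_mm`` (white-matter bundles have finite
    cross-sections; a 12 mm lesion must remove only part of an edge's
    volume).
    """
    if route == "straight":
        vox = _polyline_voxels(np.array([ci, cj]), grid)
    else:
        mid_y = (ci[1] + cj[1]) / 2.0
        mid_z = (ci[2] + cj[2]) / 2.0
        extent_z = grid.spacing[2] * (grid.shape[2] - 1) / 2.0
        if route == "callosal":
            wz = min(mid_z + 15.0 + jitter, 0.9 * extent_z)
        else:  # detour
            wz = max(mid_z - 20.0 - jitter, -0.9 * extent_z)
        waypoint = np.array([0.0, mid_y, wz])
        vox = _polyline_voxels(np.array([ci, waypoint, cj]), grid)
        if route == "callosal":
            x_mm = grid.voxel_to_world(vox)[:, 0]
            if not (np.abs(x_mm) < grid.spacing[0] / 2.0).any():
                vox = np.vstack([vox, grid.world_to_voxel(waypoint)[None, :]])
    if radius_mm > 0:
        vox = _dilate(vox, _ball_offsets(radius_mm, grid), grid)
    if route == "detour" and len(vox):
        x_mm = grid.voxel_to_world(vox)[:, 0]
        vox = vox[np.abs(x_mm) >= grid.spacing[0] / 2.0]
    return vox


def _voxel_counts(n_vox: int, rng: np.random.Generator) -> np.ndarray:
    """Per-voxel streamline counts along one directed trajectory (>= 1)."""
    return 1.0 + rng.poisson(5.0, size=n_vox)


@dataclass
class _Template:
    """Shared anatomy of a cohort: placement, expected counts, edge support.

    Region centroids come from a common atlas, so across subjects the node
    geometry, the edge support, and the trajectory routes are fixed; only
    the streamline counts vary.
    """

    ids: list[str]
    hemis: np.ndarray
    centroids: np.ndarray
    volumes: np.ndarray
    mu: np.ndarray                 # expected directed streamline counts
    sel_i: np.ndarray              # connected pair endpoints (i < j)
    sel_j: np.ndarray
    routes: list[str]


def _build_template(params: GeneratorParams, rng: np.random.Generator) -> _Template:
    n = params.n_nodes
    half = n // 2
    ids, hemis, centroids = _place_nodes(params, rng)
    volumes = rng.lognormal(np.log(params.volume_mean), 0.3, size=n)
    # hubs: mirrored pairs, chosen among node indices within each hemisphere
    hub_left = rng.choice(half, size=params.n_hubs // 2, replace=False)
    is_hub = np.zeros(n, dtype=bool)
    is_hub[np.concatenate([hub_left, hub_left + half])] = True

    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    hub_count_boost = np.sqrt(params.hub_multiplier) ** (
        is_hub[:, None].astype(int) + is_hub[None, :].astype(int)
    )
    # the callosal bottleneck: interhemispheric connections are sparser and
    # weaker than intrahemispheric ones, so left-right diffusion is the
    # slowest non-trivial mode
    cross = hemis[:, None] != hemis[None, :]
    attenuation = np.where(cross, params.inter_attenuation, 1.0)
    decay = np.exp(-d / params.decay_length_mm)
    mu = params.base_count * attenuation * decay * hub_count_boost

    iu, ju = np.triu_indices(n, k=1)
    for attempt in range(params.max_retries):
        p = np.minimum(1.0, params.connect_scale * attenuation * decay)
        connected = rng.random(len(iu)) < p[iu, ju]
        connected |= ju - iu == half  # homotopic mirror pairs always connected
        sel_i, sel_j = iu[connected], ju[connected]
        support = np.zeros((n, n), dtype=bool)
        support[sel_i, sel_j] = True
        n_comp, _ = scipy.sparse.csgraph.connected_components(support, directed=False)
        if n_comp == 1:  # also implies no isolated node
            break
    else:
        raise RuntimeError("generator failed to produce a connected edge support")

    inter = hemis[sel_i] != hemis[sel_j]
    callosal = rng.random(len(sel_i)) < params.callosal_fraction
    routes = [("callosal" if callosal[k] else "detour") if inter[k] else "straight"
              for k in range(len(sel_i))]
    return _Template(ids=ids, hemis=hemis, centroids=centroids, volumes=volumes,
                     mu=mu, sel_i=sel_i, sel_j=sel_j, routes=routes)


def _draw_connectome(
    template: _Template,
    params: GeneratorParams,
    rng: np.random.Generator,
    subject_sd: float = 0.0,
) -> Connectome:
    """Streamline-count draw on the template support (counts >= 1 per edge).

    ``subject_sd`` > 0 adds a per-edge log-normal subject effect on the
    expected counts, the source of between-subject weight variance.
    """
    si, sj = template.sel_i, template.sel_j
    factor = (rng.lognormal(0.0, subject_sd, size=len(si))
              if subject_sd > 0 else np.ones(len(si)))
    S = np.zeros_like(template.mu)
    S[si, sj] = rng.poisson(template.mu[si, sj] * factor) + 1.0
    S[sj, si] = rng.poisson(template.mu[sj, si] * factor) + 1.0
    A = build_adjacency(S, template.volumes)
    conn = Connectome(node_ids=template.ids, hemisphere=template.hemis,
                      centroids=template.centroids, volumes=template.volumes,
                      adjacency=A)
    conn.validate()
    return conn


def _build_trajectories(
    template: _Template, params: GeneratorParams, rng: np.random.Generator
) -> EdgeTrajectorySet:
    grid = params.make_grid()
    directed = {}
    for k, (i, j) in enumerate(zip(template.sel_i, template.sel_j)):
        route = template.routes[k]
        ci, cj = template.centroids[i], template.centroids[j]
        vox_fwd = _edge_route(ci, cj, grid, route, radius_mm=params.tract_radius_mm)
        vox_rev = _edge_route(cj, ci, grid, route, radius_mm=params.tract_radius_mm,
                              jitter=1.0 if route != "straight" else 0.0)
        if route != "straight" and len(vox_rev) == 0:
            vox_rev = vox_fwd
        directed[(int(i), int(j))] = (vox_fwd, _voxel_counts(len(vox_fwd), rng))
        directed[(int(j), int(i))] = (vox_rev, _voxel_counts(len(vox_rev), rng))
    traj = EdgeTrajectorySet(grid=grid, directed=directed)
    traj.build_consensus(retain_fraction=params.retain_fraction)
    return traj


def generate_connectome(
    params: GeneratorParams | None = None, seed: int | None = 0
) -> tuple[Connectome, EdgeTrajectorySet]:
    """Draw one synthetic connectome with edge trajectories.

    Connection probability and expected streamline count both decay
    exponentially with inter-centroid distance; counts between hub pairs are
    multiplied by ``hub_multiplier`` (√-multiplier for hub–non-hub pairs).
    Homotopic mirror pairs are always connected, anchoring interhemispheric
    structure.  Redraws the edge support up to ``max_retries`` times if it
    comes out disconnected, then raises.
    """
    params = params or GeneratorParams()
    rng = _rng_from(seed)
    template = _build_template(params, rng)
    conn = _draw_connectome(template, params, rng)
    traj = _build_trajectories(template, params, rng)
    return conn, traj


# --------------------------------------------------------------------------
# Cohorts (subjects x scans)
# --------------------------------------------------------------------------

@dataclass
class Subject:
    latent: Connectome
    scans: list[Connectome]
    trajectories: EdgeTrajectorySet


@dataclass
class CohortTable:
    """Subjects × scans collection sharing one voxel grid."""

    subjects: list[Subject]
    grid: Grid
    params: GeneratorParams = field(default_factory=GeneratorParams)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def all_scans(self) -> list[Connectome]:
        return [scan for s in self.subjects for scan in s.scans]

    def subject_means(self) -> list[Connectome]:
        from .eigen import average_connectomes

        return [average_connectomes(s.scans) for s in self.subjects]


def _noisy_scan(latent: Connectome, sd: float, rng: np.random.Generator) -> Connectome:
    """Latent weights times symmetric multiplicative log-normal noise."""
    n = latent.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    noise = np.ones((n, n))
    factors = rng.lognormal(0.0, sd, size=len(iu)) if sd > 0 else np.ones(len(iu))
    noise[iu, ju] = factors
    noise[ju, iu] = factors
    return latent.with_adjacency(latent.adjacency * noise)


def generate_cohort(
    params: GeneratorParams | None = None,
    n_subjects: int = 10,
    n_scans: int = 2,
    seed: int | None = 0,
) -> CohortTable:
    """Cohort of subjects with a latent connectome and noisy repeat scans.

    All subjects share one anatomical template (region centroids come from a
    common atlas, so placement, edge support, and trajectory routes are
    fixed across the cohort); each subject draws its own streamline counts
    with a per-edge log-normal subject effect (``subject_weight_sd``), and
    each scan multiplies the latent weights by i.i.d. log-normal noise
    (``scan_noise_sd``, re-symmetrized).  Per-subject randomness flows from
    substreams of ``seed`` so results are reproducible.
    """
    params = params or GeneratorParams()
    if n_subjects < 1:
        raise InvalidInputError("n_subjects must be >= 1")
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    children = root.spawn(n_subjects + 1)
    template_rng = np.random.default_rng(children[0])
    template = _build_template(params, template_rng)
    trajectories = _build_trajectories(template, params, template_rng)
    subjects = []
    for child in children[1:]:
        sub_rng = np.random.default_rng(child)
        latent = _draw_connectome(template, params, sub_rng,
                                  subject_sd=params.subject_weight_sd)
        scans = [_noisy_scan(latent, params.scan_noise_sd, sub_rng)
                 for _ in range(n_scans)]
        subjects.append(Subject(latent=latent, scans=scans,
                                trajectories=trajectories))
    return CohortTable(subjects=subjects, grid=params.make_grid(), params=params)


# --------------------------------------------------------------------------
# Callosal-agenesis variant
# --------------------------------------------------------------------------

def generate_agcc_variant(
    connectome: Connectome,
    trajectories: EdgeTrajectorySet,
    compensation: float = 0.5,
    seed: int | None = 0,
    tract_radius_mm: float = 4.0,
) -> tuple[Connectome, EdgeTrajectorySet]:
    """AgCC-like variant: callosal edges removed, partial detour compensation.

    Every edge whose consensus mask touches the midline plane x = 0 is
    zeroed; a fraction ``compensation`` of each removed weight is re-added on
    the same node pair via an inferior detour trajectory that avoids the
    midline voxel column (so a subsequent virtual callosotomy does not cut
    it).  ``compensation`` must lie in [0, 1] (no more weight may be restored
    than was removed).
    """
    from .callosotomy import callosal_edges

    if not 0 <= compensation <= 1:
        raise InvalidInputError("compensation must be in [0, 1]")
    rng = _rng_from(seed)
    grid = trajectories.grid
    cut = callosal_edges(trajectories, plane_x=0.0)
    A = connectome.adjacency.copy()
    directed = dict(trajectories.directed)
    for i, j in cut:
        w = A[i, j]
        A[i, j] = A[j, i] = 0.0
        for key in ((i, j), (j, i)):
            directed.pop(key, None)
        if compensation > 0 and w > 0:
            A[i, j] = A[j, i] = compensation * w
            ci, cj = connectome.centroids[i], connectome.centroids[j]
            fwd = _edge_route(ci, cj, grid, "detour", radius_mm=tract_radius_mm)
            rev = _edge_route(cj, ci, grid, "detour", radius_mm=tract_radius_mm,
                              jitter=1.0)
            if len(rev) == 0:
                rev = fwd
            directed[(i, j)] = (fwd, _voxel_counts(len(fwd), rng))
            directed[(j, i)] = (rev, _voxel_counts(len(rev), rng))
    out_traj = EdgeTrajectorySet(grid=grid, directed=directed)
    out_traj.build_consensus()
    return connectome.with_adjacency(A), out_traj


def toy_atlas(trajectories: EdgeTrajectorySet, n_tracts: int = 8):
    """Toy tract atlas: white-matter voxels partitioned into spatial octants.

    A desk-scale stand-in for a real white-matter tract atlas — the three
    coordinate medians of the consensus-mask union split the white matter
    into (up to) 8 blocks labelled 1..8; background is 0.
    """
    from .reliability import TractAtlas

    if n_tracts != 8:
        raise InvalidInputError("the toy atlas supports exactly 8 octant tracts")
    wm = trajectories.white_matter_voxels()
    if len(wm) == 0:
        raise InvalidInputError("no consensus voxels to partition")
    med = np.median(wm, axis=0)
    labels = np.zeros(trajectories.grid.shape, dtype=int)
    octant = 1 + 4 * (wm[:, 0] > med[0]) + 2 * (wm[:, 1] > med[1]) + (wm[:, 2] > med[2])
    labels[tuple(wm.T)] = octant
    names = {k: f"block_{k}" for k in range(1, 9)}
    return TractAtlas(grid=trajectories.grid, labels=labels, names=names)
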