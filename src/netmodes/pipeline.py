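"""End-to-end experiment orchestration.

Each experiment regenerates its synthetic inputs from the config seed, runs
one stage of the analysis, and writes TSV/JSON outputs plus a run log, so a
whole figure-level result is re-runnable from a single config file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .callosotomy import compare_groups, detect_mode_splitting, virtual_callosotomy
from .core import InvalidInputError, build_laplacian, write_connectome
from .density import classify_edges, correlate_maps, edge_density_map, rich_club_nodes
from .eigen import average_connectomes, eigendecompose, normalize_spectrum
from .lesion import importance_map, stoppage_sweep
from .reliability import aggregate_importance_by_tract, reliability_table
from .synth import GeneratorParams, generate_agcc_variant, generate_cohort, toy_atlas

__all__ = ["PipelineConfig", "run_experiment", "EXPERIMENTS"]

logger = logging.getLogger("netmodes")

# stable substream ids so stages can be re-run independently from one root seed
_STREAMS = {"eigenmodes": 1, "importance": 2, "reliability": 3,
            "richclub": 4, "callosotomy": 5}


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_experiment` (YAML with JSON fallback)."""

    out_dir: str = "netmodes_out"
    seed: int = 0
    n_subjects: int = 10
    n_scans: int = 2
    modes: tuple[int, ...] = (2, 3, 4)
    stoppages: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    lesion_diameter_mm: float = 12.0
    lesion_stride: int = 2
    null_bins: int = 100
    null_replicates: int = 10
    plane_x: float = 0.0
    agcc_compensation: float = 0.5
    atlas_path: str | None = None
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = json.loads(text)
        data = data or {}
        cfg = cls(**data)
        return cfg

    def generator_params(self) -> GeneratorParams:
        return GeneratorParams(**self.generator)

    def stream_seed(self, name: str) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[name],))


def _prepare(config: PipelineConfig, name: str) -> Path:
    out = Path(config.out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_log(out: Path, config: PipelineConfig, name: str) -> None:
    log = {"experiment": name, "netmodes_version": __version__,
           "config": asdict(config)}
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))


def _load_atlas(config: PipelineConfig, trajectories):
    if config.atlas_path is None:
        return toy_atlas(trajectories)
    import nibabel as nib

    from .reliability import TractAtlas

    img = nib.load(config.atlas_path)
    return TractAtlas(grid=trajectories.grid,
                      labels=np.asarray(img.dataobj).astype(int))


def run_experiment(name: str, config: PipelineConfig) -> dict:
    """Run one named experiment; returns a dict of result tables/paths."""
    if name not in _STREAMS:
        raise ValueError(f"unknown experiment {name!r}; choose from {sorted(_STREAMS)}")
    if name == "reliability" and config.atlas_path is not None \
            and not Path(config.atlas_path).exists():
        raise FileNotFoundError(f"atlas not found: {config.atlas_path}")
    out = _prepare(config, name)
    _write_log(out, config, name)
    logger.info("running experiment %s -> %s", name, out)
    seed = config.stream_seed(name)
    params = config.generator_params()
    return _RUNNERS[name](config, params, seed, out)


def _run_eigenmodes(config, params, seed, out) -> dict:
    cohort = generate_cohort(params, config.n_subjects, config.n_scans, seed)
    mean = average_connectomes(cohort.subject_means())
    sys = eigendecompose(build_laplacian(mean))
    pd.DataFrame({"eigenvalue": sys.eigenvalues,
                  "normalized": normalize_spectrum(sys.eigenvalues)}).to_csv(
        out / "eigenvalues.tsv", sep="\t", index_label="mode_minus_1")
    pd.DataFrame(sys.eigenvectors, index=mean.node_ids).to_csv(
        out / "eigenvectors.tsv", sep="\t")
    node_tab = pd.DataFrame({"node_id": mean.node_ids,
                             "hemisphere": mean.hemisphere,
                             "x_mm": mean.centroids[:, 0],
                             "y_mm": mean.centroids[:, 1],
                             "z_mm": mean.centroids[:, 2]})
    for mode in config.modes:
        node_tab[f"mode_{mode}"] = sys.eigenvector(mode)
    node_tab.to_csv(out / "mode_node_values.tsv", sep="\t", index=False)
    write_connectome(mean, out / "mean")
    return {"eigenvalues": sys.eigenvalues, "out_dir": out}


def _run_importance(config, params, seed, out) -> dict:
    cohort = generate_cohort(params, 1, 1, seed)
    conn, traj = cohort.subjects[0].latent, cohort.subjects[0].trajectories
    table = stoppage_sweep(conn, traj, modes=tuple(config.modes),
                           stoppages=tuple(config.stoppages),
                           stride=config.lesion_stride,
                           diameter=config.lesion_diameter_mm)
    table.to_csv(out / "stoppage_correlations.tsv", sep="\t", index=False)
    imap = importance_map(conn, traj, mode=config.modes[0],
                          stride=config.lesion_stride,
                          diameter=config.lesion_diameter_mm)
    imap.to_tsv(out / f"importance_mode{config.modes[0]}.tsv")
    imap.to_nifti(out / f"importance_mode{config.modes[0]}.nii.gz")
    return {"correlations": table, "out_dir": out}


def _run_reliability(config, params, seed, out) -> dict:
    cohort = generate_cohort(params, config.n_subjects, config.n_scans, seed)
    atlas = _load_atlas(config, cohort.subjects[0].trajectories)
    per_scan = {}
    for s, subject in enumerate(cohort.subjects):
        for k, scan in enumerate(subject.scans):
            imap = importance_map(scan, subject.trajectories,
                                  mode=config.modes[0],
                                  stride=config.lesion_stride,
                                  diameter=config.lesion_diameter_mm)
            per_scan[(s, k)] = aggregate_importance_by_tract(imap, atlas)
    values = pd.DataFrame(per_scan).T
    values.index.names = ["subject", "scan"]
    table = reliability_table(values)
    table.to_csv(out / "reliability.tsv", sep="\t")
    return {"reliability": table, "out_dir": out}


def _run_richclub(config, params, seed, out) -> dict:
    cohort = generate_cohort(params, 1, 1, seed)
    conn, traj = cohort.subjects[0].latent, cohort.subjects[0].trajectories
    rich = rich_club_nodes(conn)
    classes = classify_edges(conn, rich)
    classes.table.to_csv(out / "edge_classes.tsv", sep="\t", index=False)
    wm = traj.white_matter_voxels()
    mask = np.zeros(traj.grid.shape, dtype=bool)
    mask[tuple(wm.T)] = True
    rows = []
    imap = importance_map(conn, traj, mode=config.modes[0],
                          stride=config.lesion_stride,
                          diameter=config.lesion_diameter_mm)
    corr_mask = mask & imap.evaluated
    for cat in ("RC", "FC", "LC"):
        dmap = edge_density_map(traj, classes.edges_in_class(cat), category=cat)
        try:
            r, ci = correlate_maps(imap.values, dmap.values, corr_mask)
        except InvalidInputError:
            logger.warning("density map for %s constant on mask; "
                           "correlation undefined", cat)
            r, ci = float("nan"), (float("nan"), float("nan"))
        rows.append({"category": cat, "mode": config.modes[0],
                     "r": r, "ci_low": ci[0], "ci_high": ci[1]})
    table = pd.DataFrame(rows)
    table.to_csv(out / "density_correlations.tsv", sep="\t", index=False)
    return {"correlations": table, "out_dir": out}


def _run_callosotomy(config, params, seed, out) -> dict:
    cohort = generate_cohort(params, config.n_subjects, 1, seed)
    controls = [s.latent for s in cohort.subjects]
    callos, agcc = [], []
    child = np.random.SeedSequence(entropy=config.seed, spawn_key=(99,))
    agcc_seeds = child.spawn(len(cohort.subjects))
    for subject, aseed in zip(cohort.subjects, agcc_seeds):
        cut_conn, _ = virtual_callosotomy(subject.latent, subject.trajectories,
                                          plane_x=config.plane_x)
        callos.append(cut_conn)
        agcc_conn, _ = generate_agcc_variant(
            subject.latent, subject.trajectories,
            compensation=config.agcc_compensation,
            seed=np.random.default_rng(aseed))
        agcc.append(agcc_conn)
    comparison = compare_groups({"control": controls, "agcc": agcc,
                                 "callosotomy": callos},
                                reference_group="control")
    comparison.per_subject.to_csv(out / "lambda2_per_subject.tsv", sep="\t", index=False)
    comparison.summary.to_csv(out / "lambda2_summary.tsv", sep="\t")
    comparison.ttests.to_csv(out / "lambda2_ttests.tsv", sep="\t", index=False)
    ctrl_sys = eigendecompose(build_laplacian(average_connectomes(controls)))
    cut_sys = eigendecompose(build_laplacian(average_connectomes(callos)))
    report = detect_mode_splitting(ctrl_sys, cut_sys,
                                   controls[0].hemisphere, top_k=3)
    report.table.to_csv(out / "mode_splitting.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(
        comparison.summary.to_json(orient="index", indent=2))
    return {"comparison": comparison, "splitting": report, "out_dir": out}


_RUNNERS = {
    "eigenmodes": _run_eigenmodes,
    "importance": _run_importance,
    "reliability": _run_reliability,
    "richclub": _run_richclub,
    "callosotomy": _run_callosotomy,
}

EXPERIMENTS = tuple(_RUNNERS)
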