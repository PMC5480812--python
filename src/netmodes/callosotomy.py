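"""Virtual callosotomy, group eigenspectrum comparison, and mode splitting.

A virtual callosotomy removes every edge whose trajectory passes through the
corpus callosum, modelled as a midline sagittal plane: an edge is cut
(weight set to zero, exclusion-mask semantics) if its consensus mask
contains a voxel whose center lies within half a voxel of the plane.

Without callosal edges the two hemispheres (nearly) decouple, so each slow
eigenmode of the intact network splits into a pair of single-hemisphere
modes, and the second eigenvalue — the rate of left–right diffusion —
drops.  Congenital callosal agenesis (AgCC) differs from surgical
callosotomy by compensatory non-callosal interhemispheric routes, which
raise the second eigenvalue back toward (but not to) the intact value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import Connectome, EdgeTrajectorySet, InvalidInputError, build_laplacian
from .eigen import (
    DEFAULT_MATCH_WINDOW,
    EigenSystem,
    average_connectomes,
    eigendecompose,
    match_eigenmode,
    normalize_spectrum,
)

__all__ = [
    "virtual_callosotomy",
    "GroupComparison",
    "compare_groups",
    "SplitReport",
    "detect_mode_splitting",
    "callosal_edges",
]

DEFAULT_SPLIT_SUPPORT = 0.9


def callosal_edges(
    trajectories: EdgeTrajectorySet, plane_x: float = 0.0
) -> list[tuple[int, int]]:
    """Edges whose consensus mask touches the midline plane x = plane_x.

    A mask voxel touches the plane when its center's x coordinate is within
    half an x-spacing of the plane.
    """
    grid = trajectories.grid
    half = grid.spacing[0] / 2.0
    x0, nx = grid.origin[0], grid.shape[0]
    if not (x0 - half <= plane_x <= x0 + grid.spacing[0] * (nx - 1) + half):
        raise InvalidInputError("midline plane does not intersect the grid")
    hits = []
    for key, mask in trajectories.consensus.items():
        if len(mask) == 0:
            continue
        x_mm = grid.voxel_to_world(mask)[:, 0]
        if np.any(np.abs(x_mm - plane_x) < half + 1e-12):
            hits.append(key)
    return sorted(hits)


def virtual_callosotomy(
    connectome: Connectome,
    trajectories: EdgeTrajectorySet,
    plane_x: float = 0.0,
) -> tuple[Connectome, list[tuple[int, int]]]:
    """Zero every edge crossing the midline plane; return (connectome, cut list).

    Edges are cut entirely (streamlines through the callosum are excluded),
    not proportionally weakened.  A resulting disconnection is expected and
    flagged with a warning rather than an error.
    """
    cut = callosal_edges(trajectories, plane_x)
    A = connectome.adjacency.copy()
    for i, j in cut:
        A[i, j] = 0.0
        A[j, i] = 0.0
    out = connectome.with_adjacency(A)
    lam = eigendecompose(build_laplacian(out)).eigenvalues
    if len(lam) > 1 and lam[1] <= 1e-9 * max(lam[-1], 1.0):
        warnings.warn("virtual callosotomy disconnected the graph")
    return out, cut


@dataclass
class GroupComparison:
    """Per-subject matched second eigenvalues and group-level statistics."""

    per_subject: pd.DataFrame   # group, subject, lambda2_raw, lambda2_norm, ...
    summary: pd.DataFrame       # per group: n, mean, ci_low, ci_high
    ttests: pd.DataFrame        # pairwise two-sample t-tests on lambda2_norm


def compare_groups(
    cohorts: dict[str, list[Connectome]],
    reference_group: str | None = None,
    mode: int = 2,
    window: int | None = DEFAULT_MATCH_WINDOW,
) -> GroupComparison:
    """Compare the normalized second eigenvalue across subject groups.

    Per subject, the Laplacian is eigendecomposed, the spectrum normalized by
    its mean, and the eigenvalue of the mode matched to the reference group's
    mean-connectome eigenmode extracted.  The normalization is reported both
    including and excluding zero eigenvalues (``lambda2_norm`` /
    ``lambda2_norm_nonzero``).  Groups are summarised by mean and t-based
    95% CI, and compared pairwise by two-sample t-tests (alpha = 0.05, no
    multiple-testing correction).
    """
    if not cohorts or any(len(v) == 0 for v in cohorts.values()):
        raise InvalidInputError("every cohort must be nonempty")
    ref_name = reference_group or next(iter(cohorts))
    ref_sys = eigendecompose(build_laplacian(average_connectomes(cohorts[ref_name])))
    ref_vec = ref_sys.eigenvector(mode)

    rows = []
    for group, members in cohorts.items():
        for s, conn in enumerate(members):
            sys = eigendecompose(build_laplacian(conn))
            m = match_eigenmode(ref_vec, mode, sys, window=window)
            lam_raw = sys.eigenvalue(m.matched_index)
            norm_all = normalize_spectrum(sys.eigenvalues, include_zero=True)
            norm_nz = normalize_spectrum(sys.eigenvalues, include_zero=False)
            rows.append({
                "group": group, "subject": s,
                "matched_index": m.matched_index,
                "lambda2_raw": lam_raw,
                "lambda2_norm": float(norm_all[m.matched_index - 1]),
                "lambda2_norm_nonzero": float(norm_nz[m.matched_index - 1]),
            })
    per_subject = pd.DataFrame(rows)

    summary_rows = []
    for group, sub in per_subject.groupby("group", sort=False):
        x = sub["lambda2_norm"].to_numpy()
        mean = float(np.mean(x))
        if len(x) >= 2:
            sem = np.std(x, ddof=1) / np.sqrt(len(x))
            t = scipy.stats.t.ppf(0.975, df=len(x) - 1)
            lo, hi = mean - t * sem, mean + t * sem
        else:
            warnings.warn(f"cohort '{group}' has one subject; CI undefined")
            lo = hi = float("nan")
        summary_rows.append({"group": group, "n": len(x), "mean": mean,
                             "ci_low": lo, "ci_high": hi})
    summary = pd.DataFrame(summary_rows).set_index("group")

    tt_rows = []
    names = list(cohorts)
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            xa = per_subject.loc[per_subject.group == a, "lambda2_norm"]
            xb = per_subject.loc[per_subject.group == b, "lambda2_norm"]
            if xa.nunique() <= 1 and xb.nunique() <= 1 and xa.iloc[0] == xb.iloc[0]:
                stat, p = 0.0, 1.0
            else:
                stat, p = scipy.stats.ttest_ind(xa, xb)
            tt_rows.append({"group_a": a, "group_b": b, "t": float(stat),
                            "p": float(p), "significant": bool(p < 0.05)})
    return GroupComparison(per_subject=per_subject, summary=summary,
                           ttests=pd.DataFrame(tt_rows))


@dataclass
class SplitReport:
    """Mapping of intact-network modes onto lesioned-network mode pairs."""

    table: pd.DataFrame   # per control mode: mapped indices, supports, split flag

    def split_modes(self) -> list[int]:
        return self.table.loc[self.table["split"], "control_mode"].astype(int).tolist()


def detect_mode_splitting(
    control: EigenSystem,
    lesioned: EigenSystem,
    hemisphere: np.ndarray,
    top_k: int = 3,
    support_threshold: float = DEFAULT_SPLIT_SUPPORT,
    min_inner: float = 0.35,
) -> SplitReport:
    """Detect intact-network eigenmodes splitting into per-hemisphere pairs.

    For each control mode 2 .. top_k+1, the two lesioned modes with the
    largest |inner product| are found.  Each lesioned mode's hemispheric
    support is the share of its squared vector mass in the left / right
    hemisphere (the two shares sum to 1).  A *split* is declared when the
    control mode genuinely projects onto both mapped modes (each |inner
    product| >= ``min_inner``; an exact half-half split gives 1/sqrt(2) ~
    0.71 on each) and the two mapped modes each carry at least
    ``support_threshold`` of their mass in opposite hemispheres.
    """
    hemisphere = np.asarray(hemisphere)
    if len(hemisphere) != control.n_modes or control.n_modes != lesioned.n_modes:
        raise InvalidInputError("node count mismatch between systems and labels")
    left = hemisphere == hemisphere[0]  # first node's side is "left" reference
    is_left = hemisphere == "L" if "L" in hemisphere else left

    rows = []
    for mode in range(2, 2 + top_k):
        v = control.eigenvector(mode)
        inner = np.abs(lesioned.eigenvectors.T @ v)
        top2 = np.argsort(-inner, kind="stable")[:2]
        supports = []
        for idx in top2:
            u = lesioned.eigenvectors[:, idx]
            supports.append(float(np.sum(u[is_left] ** 2) / np.sum(u**2)))
        s1, s2 = supports
        shared = min(inner[top2[0]], inner[top2[1]]) >= min_inner
        split = shared and (
            (s1 >= support_threshold and (1 - s2) >= support_threshold)
            or (s2 >= support_threshold and (1 - s1) >= support_threshold))
        rows.append({
            "control_mode": mode,
            "mapped_mode_1": int(top2[0]) + 1,
            "mapped_mode_2": int(top2[1]) + 1,
            "inner_1": float(inner[top2[0]]),
            "inner_2": float(inner[top2[1]]),
            "left_support_1": s1,
            "left_support_2": s2,
            "split": bool(split),
        })
    return SplitReport(table=pd.DataFrame(rows))
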