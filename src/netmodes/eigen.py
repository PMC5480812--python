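"""Laplacian eigendecomposition, eigenmode matching, and the diffusion solver.

The network diffusion model dx/dt = −βLx is solved by the eigendecomposition
L = QΛQᵀ: each eigenmode (column of Q) decays independently at rate βλ, so
the low-eigenvalue ("slow") modes carry the persistent, large-scale spread
patterns.  Mode 1 (λ = 0, constant vector on a connected graph) is the
steady state; mode 2 is the slowest non-trivial pattern — in two-hemisphere
brain networks it is interhemispheric diffusion.

Because eigenvalue order can swap between subjects when neighbouring
eigenvalues are close, cross-subject comparisons first *match* modes by the
absolute inner product against a reference eigenvector (sign is arbitrary),
searching a small window of ranks around the reference rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.stats

from .core import CHECK_RTOL, Connectome, InvalidInputError, LaplacianMatrix

__all__ = [
    "EigenSystem",
    "MatchResult",
    "AngleVariance",
    "eigendecompose",
    "match_eigenmode",
    "angle_variance",
    "normalize_spectrum",
    "solve_network_diffusion",
    "average_connectomes",
]

#: default matching window (ranks searched either side of the reference rank);
#: matched modes are empirically always within two steps of the reference.
DEFAULT_MATCH_WINDOW = 2


@dataclass
class EigenSystem:
    """Ascending eigenvalues and orthonormal eigenvectors of a Laplacian."""

    eigenvalues: np.ndarray   # (N,), ascending, λ1 ≈ 0
    eigenvectors: np.ndarray  # (N, N), column k-1 = mode k

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def eigenvalue(self, mode: int) -> float:
        """Eigenvalue of 1-based ``mode`` (mode 1 = zero mode)."""
        return float(self.eigenvalues[mode - 1])

    def eigenvector(self, mode: int) -> np.ndarray:
        """Unit eigenvector of 1-based ``mode``."""
        return self.eigenvectors[:, mode - 1]

    def n_zero_modes(self, rtol: float = CHECK_RTOL) -> int:
        """Number of (numerically) zero eigenvalues = connected components."""
        scale = max(abs(self.eigenvalues[-1]), 1.0)
        return int(np.sum(np.abs(self.eigenvalues) <= rtol * scale * 1e3))


def eigendecompose(L: LaplacianMatrix | np.ndarray) -> EigenSystem:
    """Full symmetric eigendecomposition with deterministic ordering and signs.

    Eigenvalues are sorted ascending (ties kept in LAPACK's stable order);
    each eigenvector's sign is fixed so its largest-magnitude entry is
    positive.  Degenerate eigenvalues return an orthonormal basis of the
    eigenspace.
    """
    M = L.matrix if isinstance(L, LaplacianMatrix) else np.asarray(L, dtype=float)
    scale = max(np.abs(M).max(), 1.0) if M.size else 1.0
    if not np.allclose(M, M.T, atol=CHECK_RTOL * scale):
        raise InvalidInputError("matrix must be symmetric")
    vals, vecs = scipy.linalg.eigh(M)
    # deterministic sign: largest-|entry| component positive
    for k in range(vecs.shape[1]):
        col = vecs[:, k]
        lead = np.argmax(np.abs(col))
        if col[lead] < 0:
            vecs[:, k] = -col
    return EigenSystem(eigenvalues=vals, eigenvectors=vecs)


@dataclass
class MatchResult:
    """Best-matching mode of a candidate system for a reference eigenvector."""

    matched_index: int      # 1-based mode index in the candidate system
    sign: int               # ±1 so that sign * v_matched aligns with reference
    inner_product: float    # |v̄ᵀ v_matched| ∈ [0, 1]
    step_offset: int        # |matched_index − reference_index|


def match_eigenmode(
    reference: np.ndarray,
    reference_index: int,
    candidates: EigenSystem,
    window: int | None = DEFAULT_MATCH_WINDOW,
) -> MatchResult:
    """Find the candidate eigenmode most similar to a reference eigenvector.

    Searches candidate modes within ``window`` ranks of ``reference_index``
    (1-based; ``window=None`` searches all modes) and returns the one
    maximising the absolute inner product, with the sign that aligns it to
    the reference.  Eigenvectors are sign-ambiguous, hence the absolute
    value.
    """
    v = np.asarray(reference, dtype=float)
    if v.ndim != 1 or len(v) != candidates.eigenvectors.shape[0]:
        raise InvalidInputError("reference vector dimension mismatch")
    n = candidates.n_modes
    if window is None or not np.isfinite(window):
        lo, hi = 1, n
    else:
        if window < 0:
            raise InvalidInputError("window must be >= 0")
        lo = max(1, reference_index - int(window))
        hi = min(n, reference_index + int(window))
    cols = candidates.eigenvectors[:, lo - 1:hi]
    inner = cols.T @ v
    best_local = int(np.argmax(np.abs(inner)))
    best = lo + best_local
    ip = inner[best_local]
    if np.abs(ip) == 0:
        warnings.warn("reference orthogonal to all candidates in window; "
                      "returning best (zero) match")
    sign = 1 if ip >= 0 else -1
    return MatchResult(
        matched_index=best,
        sign=sign,
        inner_product=float(abs(ip)),
        step_offset=abs(best - reference_index),
    )


@dataclass
class AngleVariance:
    """Per-subject angles (degrees) to a reference mode, with group summary."""

    angles_deg: np.ndarray
    mean: float
    ci95: tuple[float, float]


def _mean_ci95(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    x = np.asarray(x, dtype=float)
    m = float(np.mean(x))
    if len(x) < 2:
        return m, (np.nan, np.nan)
    sem = np.std(x, ddof=1) / np.sqrt(len(x))
    t = scipy.stats.t.ppf(0.975, df=len(x) - 1)
    return m, (m - t * sem, m + t * sem)


def angle_variance(
    reference: np.ndarray,
    reference_index: int,
    subject_systems: list[EigenSystem],
    window: int | None = DEFAULT_MATCH_WINDOW,
) -> AngleVariance:
    """Angle between a reference eigenmode and each subject's matched mode.

    For each subject the angle is minimised over the matching window and
    over sign: σθ = acos(max_j |v̄ᵀ v_j|), reported in degrees in [0, 90].
    The acos argument is clipped to [−1, 1] to absorb rounding.
    """
    v = np.asarray(reference, dtype=float)
    angles = []
    for sys in subject_systems:
        m = match_eigenmode(v, reference_index, sys, window=window)
        angles.append(np.degrees(np.arccos(np.clip(m.inner_product, -1.0, 1.0))))
    angles = np.asarray(angles)
    mean, ci = _mean_ci95(angles)
    return AngleVariance(angles_deg=angles, mean=mean, ci95=ci)


def normalize_spectrum(eigenvalues: np.ndarray, include_zero: bool = True) -> np.ndarray:
    """Divide each eigenvalue by the spectrum mean (output mean = 1).

    Normalisation makes eigenvalue *distributions* comparable between
    subjects whose overall connection strength differs.  By default the mean
    includes the zero eigenvalue(s); ``include_zero=False`` is available for
    sensitivity analysis.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise InvalidInputError("empty spectrum")
    denom = lam.mean() if include_zero else lam[np.abs(lam) > 0].mean() if np.any(np.abs(lam) > 0) else 0.0
    if denom == 0:
        raise ZeroDivisionError("cannot normalize an all-zero spectrum")
    return lam / denom


def solve_network_diffusion(
    L: LaplacianMatrix | np.ndarray,
    x0: np.ndarray,
    beta: float = 1.0,
    t: float = 0.0,
    system: EigenSystem | None = None,
) -> np.ndarray:
    """Solve dx/dt = −βLx: x(t) = Q exp(−Λβt) Qᵀ x0.

    For symmetric L the total Σx is conserved (the zero mode carries the
    mean); on a connected graph x(t) → uniform as t → ∞.  Pass a
    precomputed ``system`` to reuse an eigendecomposition.
    """
    if beta <= 0:
        raise InvalidInputError("beta must be positive")
    if t < 0:
        raise InvalidInputError("t must be non-negative")
    sys = system if system is not None else eigendecompose(L)
    x0 = np.asarray(x0, dtype=float)
    if len(x0) != sys.n_modes:
        raise InvalidInputError("state vector dimension mismatch")
    coeff = sys.eigenvectors.T @ x0
    return sys.eigenvectors @ (np.exp(-sys.eigenvalues * beta * t) * coeff)


def average_connectomes(connectomes: list[Connectome]) -> Connectome:
    """Entrywise mean adjacency over connectomes with identical node sets.

    Metadata (ids, hemispheres, centroids, volumes) is taken from the first
    input.
    """
    if not connectomes:
        raise InvalidInputError("need at least one connectome")
    first = connectomes[0]
    for c in connectomes[1:]:
        if c.node_ids != first.node_ids:
            raise InvalidInputError("connectomes have differing node sets/orderings")
    mean_A = np.mean([c.adjacency for c in connectomes], axis=0)
    return first.with_adjacency(mean_A)
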