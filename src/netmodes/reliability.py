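"""Tract-level aggregation of importance maps and test–retest ICC.

Reliability of a voxel map is assessed at the tract level: importance is
averaged over the voxels of each white-matter tract (any integer label
volume on the working grid), and the intraclass correlation coefficient of
the per-tract means is computed over subjects scanned twice:

    sigma1_r = mean over subjects of Var({i_s,r,1, i_s,r,2})     (within)
    sigma2_r = Var over subjects of (i_s,r,1 + i_s,r,2) / 2      (between)
    ICC_r    = sigma2_r / (sigma1_r + sigma2_r)

Sample variance (n−1 denominator) is used throughout; with two scans per
subject and an equal design the ICC ratio itself is convention-invariant.
Clinical reporting bands: ICC < 0.4 poor, 0.4–0.75 fair-to-good, > 0.75
excellent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Grid, InvalidInputError
from .lesion import ImportanceMap

__all__ = ["TractAtlas", "aggregate_importance_by_tract", "icc",
           "reliability_table", "icc_band"]


@dataclass
class TractAtlas:
    """Integer label volume on the working grid (0 = background)."""

    grid: Grid
    labels: np.ndarray                      # int volume, same shape as grid
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if tuple(self.labels.shape) != tuple(self.grid.shape):
            raise InvalidInputError("atlas labels do not match grid shape")

    @property
    def tract_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(t) for t in ids if t != 0]

    def name(self, tract: int) -> str:
        return self.names.get(tract, f"tract_{tract}")


def aggregate_importance_by_tract(
    imap: ImportanceMap, atlas: TractAtlas, evaluated_only: bool = True
) -> pd.Series:
    """Mean importance per tract (background label 0 excluded).

    By default only voxels actually evaluated as lesion centres contribute
    (strided maps are zero elsewhere by construction, which would otherwise
    dilute the mean).  Empty tracts get NaN with a warning.
    """
    if tuple(imap.grid.shape) != tuple(atlas.grid.shape):
        raise InvalidInputError("importance map and atlas grids differ")
    sel = imap.evaluated if evaluated_only else np.ones(imap.values.shape, bool)
    out = {}
    for t in atlas.tract_ids:
        vox = (atlas.labels == t) & sel
        if not vox.any():
            warnings.warn(f"tract {t} contains no evaluated voxels")
            out[atlas.name(t)] = np.nan
        else:
            out[atlas.name(t)] = float(imap.values[vox].mean())
    return pd.Series(out, name="mean_importance")


def icc(values: np.ndarray) -> tuple[float, float, float]:
    """Variance-ratio ICC of a (subjects × scans) value table for one tract.

    Returns (sigma1, sigma2, ICC) with sigma1 the mean within-subject scan
    variance, sigma2 the between-subject variance of scan means.  Designed
    for two scans per subject; more scans use the same per-subject variance.
    When both variances vanish the ICC is undefined and NaN is returned with
    a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
        raise InvalidInputError("need >= 2 subjects and >= 2 scans per subject")
    sigma1 = float(np.mean(np.var(v, axis=1, ddof=1)))
    sigma2 = float(np.var(np.mean(v, axis=1), ddof=1))
    if sigma1 + sigma2 == 0:
        warnings.warn("within- and between-subject variance both zero; ICC undefined")
        return sigma1, sigma2, float("nan")
    return sigma1, sigma2, sigma2 / (sigma1 + sigma2)


def icc_band(value: float) -> str:
    """Clinical reliability band label for an ICC value."""
    if np.isnan(value):
        return "undefined"
    if value < 0.4:
        return "poor"
    if value <= 0.75:
        return "fair-to-good"
    return "excellent"


def reliability_table(
    tract_values: pd.DataFrame | dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-tract reliability summary.

    ``tract_values`` maps tract name to a (subjects × scans) array (or is a
    DataFrame with a MultiIndex (subject, scan) and one column per tract).
    Returns a table with columns mean, sd, sigma1, sigma2, ICC, band.
    """
    if isinstance(tract_values, pd.DataFrame):
        arrays = {
            c: tract_values[c].unstack(level=-1).to_numpy(float)
            for c in tract_values.columns
        }
    else:
        arrays = {k: np.asarray(v, float) for k, v in tract_values.items()}
    rows = []
    for tract, v in arrays.items():
        s1, s2, r = icc(v)
        rows.append({"tract": tract, "mean": float(np.mean(v)),
                     "sd": float(np.std(v, ddof=1)), "sigma1": s1,
                     "sigma2": s2, "ICC": r, "band": icc_band(r)})
    return pd.DataFrame(rows).set_index("tract")
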