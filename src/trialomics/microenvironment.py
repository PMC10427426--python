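"""Multiplex-immunofluorescence quantification.

Cells arrive as coordinate/phenotype tables (one boolean column per
marker, coordinates in microns).  The module computes marker-positive
cell densities per mm^2 of analysed tissue, per-cell distances to the
nearest cytokeratin-positive (CK+) tumor cell with half-open 10 um
binning, and paired baseline / on-treatment Wilcoxon signed-rank
statistics with Benjamini-Hochberg adjustment across marker or bin
families.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .her2_spatial import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "MARKERS",
    "density",
    "nearest_ck_distance",
    "bin_distances",
    "paired_test",
    "paired_test_batch",
    "tissue_area_from_cells",
]

MARKERS = ("CD3", "CD4", "CD8", "CD68", "FoxP3", "PD1", "PDL1", "CK")


def _marker_mask(cells: pd.DataFrame, marker_query: Iterable[str] | str) -> np.ndarray:
    """Boolean mask of cells positive for every queried marker (AND)."""
    if isinstance(marker_query, str):
        marker_query = [marker_query]
    mask = np.ones(len(cells), dtype=bool)
    for m in marker_query:
        if m not in cells.columns:
            raise KeyError(f"marker column {m!r} absent from cell table")
        mask &= cells[m].astype(bool).to_numpy()
    return mask


def density(
    cells: pd.DataFrame, marker_query: Iterable[str] | str, tissue_area_mm2: float
) -> float:
    """Cells positive for the marker combination per mm^2 of tissue."""
    if tissue_area_mm2 <= 0:
        raise ValueError("tissue area must be positive")
    if len(cells) == 0:
        return 0.0
    return float(_marker_mask(cells, marker_query).sum()) / tissue_area_mm2


def nearest_ck_distance(cells: pd.DataFrame, ck_column: str = "CK") -> pd.Series:
    """Per-cell Euclidean distance (um) to the nearest CK+ cell.

    CK+ cells measure to the nearest *other* CK+ cell; requires at
    least one CK+ reference cell (two for CK+ cells themselves).
    """
    if ck_column not in cells.columns:
        raise KeyError(f"no {ck_column!r} column in cell table")
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    is_ck = cells[ck_column].astype(bool).to_numpy()
    if not is_ck.any():
        raise ValueError("no CK+ reference cell present")
    tree = cKDTree(xy[is_ck])
    out = np.empty(len(cells))
    non_ck = ~is_ck
    if non_ck.any():
        d, _ = tree.query(xy[non_ck], k=1)
        out[non_ck] = d
    if is_ck.any():
        if is_ck.sum() < 2:
            out[is_ck] = np.nan
        else:
            # k=2: first neighbour is the cell itself at distance 0
            d, _ = tree.query(xy[is_ck], k=2)
            out[is_ck] = d[:, 1]
    return pd.Series(out, index=cells.index, name="nearest_ck_um")


def bin_distances(
    distances: Sequence[float], width: float = 10.0, n_bins: Optional[int] = None
) -> pd.Series:
    """Counts over half-open distance bins [0,w), [w,2w), ...

    A distance exactly on an edge falls in the upper bin.  ``n_bins``
    defaults to covering the largest finite distance.
    """
    d = np.asarray(distances, float)
    d = d[np.isfinite(d)]
    if n_bins is None:
        n_bins = int(d.max() // width) + 1 if d.size else 1
    idx = np.floor(d / width).astype(int)
    counts = np.bincount(idx[idx < n_bins], minlength=n_bins)
    labels = [f"[{i * width:g},{(i + 1) * width:g})" for i in range(n_bins)]
    return pd.Series(counts, index=labels, name="count")


def paired_test(
    baseline: Sequence[float], on_treatment: Sequence[float], exact_max: int = 25
) -> float:
    """Two-sided Wilcoxon matched-pairs signed-rank p-value.

    Zero differences are dropped (Wilcoxon's original rule); the exact
    null is used for up to ``exact_max`` non-zero differences when the
    ranks are tie-free, otherwise the normal approximation with tie
    and continuity corrections.  All-zero differences give p = 1 with
    a warning.
    """
    b = np.asarray(baseline, float)
    t = np.asarray(on_treatment, float)
    if b.shape != t.shape:
        raise ValueError("paired samples must have equal length")
    diffs = t - b
    nz = diffs[diffs != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p-value set to 1", stacklevel=2)
        return 1.0
    has_ties = len(np.unique(np.abs(nz))) < nz.size
    if nz.size <= exact_max and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                         correction=(method == "approx"), method=method)
    return float(res.pvalue)


def paired_test_batch(
    pairs_by_family: dict[str, tuple[Sequence[float], Sequence[float]]]
) -> pd.DataFrame:
    """Wilcoxon signed-rank across a family of markers/bins with
    Benjamini-Hochberg adjustment; returns a tidy frame with columns
    family, p, q."""
    names = list(pairs_by_family)
    ps = [paired_test(*pairs_by_family[n]) for n in names]
    qs = benjamini_hochberg(ps)
    return pd.DataFrame({"family": names, "p": ps, "q": qs})


def tissue_area_from_cells(cells: pd.DataFrame, buffer_um: float = 20.0) -> float:
    """Tissue area (mm^2) as a buffered convex hull ('alpha-shape'
    surrogate) of the cell cloud, for tables without an explicit area."""
    from shapely.geometry import MultiPoint

    if len(cells) < 3:
        raise ValueError("need at least three cells to estimate an area")
    hull = MultiPoint(cells[["x_um", "y_um"]].to_numpy(float)).convex_hull.buffer(buffer_um)
    return float(hull.area) / 1e6
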