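"""Spatial autocorrelation and hot/cold-spot statistics on raster surfaces.

Global Moran's I measures whether a surface is spatially clustered
(I > 0), random (I ≈ E[I] = −1/(n−1)) or dispersed (I < 0); its z-score
uses the randomization-assumption variance.  The Getis-Ord Gi* statistic
scores each cell's neighbourhood (self included) against the global mean
and flags hotspots (clusters of high values) and coldspots (low values)
at the 90/95/99% confidence tiers ±1.645/±1.960/±2.576.

Neighbourhoods are rook (4 adjacent cells) or queen (8, the default)
contiguity on the raster lattice; nodata cells are removed from the
weights graph entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .raster_io import Grid

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "HotspotMap",
    "HOTSPOT_CLASSES",
    "contiguity_matrix",
    "morans_i",
    "gi_star",
]

# class code -> label, ordered cold to hot; code 0 is not significant
HOTSPOT_CLASSES = {
    -3: "coldspot99",
    -2: "coldspot95",
    -1: "coldspot90",
    0: "not_significant",
    1: "hotspot90",
    2: "hotspot95",
    3: "hotspot99",
}
_Z_TIERS = (1.645, 1.960, 2.576)  # 90 / 95 / 99 %


@dataclass
class SpatialWeights:
    """Contiguity scheme for the raster weights graph."""

    scheme: str = "queen"
    row_standardized: bool = True
    include_self: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in ("rook", "queen"):
            raise ValueError("scheme must be 'rook' or 'queen'")


@dataclass
class MoranResult:
    I: float
    expected: float
    z: float
    variance: float
    n: int


@dataclass
class HotspotMap:
    """Per-cell hot/cold classification and its area breakdown."""

    classes: Grid  # codes -3..3 per HOTSPOT_CLASSES
    z_scores: Grid
    percents: pd.Series  # index: the seven class labels

    def __post_init__(self) -> None:
        if list(self.percents.index) != [HOTSPOT_CLASSES[c] for c in sorted(HOTSPOT_CLASSES)]:
            raise ValueError("percents must cover the seven classes in order")
        if not math.isclose(float(self.percents.sum()), 100.0, abs_tol=1e-9):
            raise ValueError("class percentages must sum to 100")


def contiguity_matrix(
    mask: np.ndarray, scheme: str = "queen"
) -> sparse.csr_matrix:
    """Binary contiguity matrix (no self-loops) over the True cells of ``mask``.

    Cells are numbered row-major over the valid cells; the relation is
    symmetric by construction.
    """
    idx = np.full(mask.shape, -1, dtype=int)
    idx[mask] = np.arange(mask.sum())
    offsets = [(0, 1), (1, 0)]
    if scheme == "queen":
        offsets += [(1, 1), (1, -1)]
    rows, cols = [], []
    for dr, dc in offsets:
        a = np.zeros(mask.shape, dtype=bool)
        # pair each cell with its (dr, dc)-shifted neighbour when both valid
        r0, r1 = max(0, -dr), mask.shape[0] - max(0, dr)
        c0, c1 = max(0, -dc), mask.shape[1] - max(0, dc)
        a[r0:r1, c0:c1] = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        src = idx[a]
        dst_rows, dst_cols = np.nonzero(a)
        dst = idx[dst_rows + dr, dst_cols + dc]
        rows.extend([src, dst])
        cols.extend([dst, src])
    n = int(mask.sum())
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        w = sparse.csr_matrix((np.ones(len(r)), (r, c)), shape=(n, n))
    else:
        w = sparse.csr_matrix((n, n))
    return w


def morans_i(values: Grid, weights: SpatialWeights | None = None) -> MoranResult:
    """Global Moran's I with expectation −1/(n−1) and randomization z-score.

    Raises on a constant surface (zero variance) or fewer than 2 valid cells.
    """
    weights = weights or SpatialWeights()
    mask = values.valid_mask
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 valid cells")
    x = values.values[mask]
    z = x - x.mean()
    m2 = float(z @ z)
    if m2 == 0.0:
        raise ValueError("zero variance: Moran's I undefined on a constant surface")

    w = contiguity_matrix(mask, weights.scheme).astype(float)
    if weights.row_standardized:
        deg = np.asarray(w.sum(axis=1)).ravel()
        deg[deg == 0] = 1.0
        w = sparse.diags(1.0 / deg) @ w

    s0 = float(w.sum())
    num = float(z @ (w @ z))
    I = (n / s0) * num / m2

    e_i = -1.0 / (n - 1)
    a = (w + w.T).tocsr()
    s1 = 0.5 * float(a.multiply(a).sum())
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2 = float(((row + col) ** 2).sum())
    b2 = n * float((z**4).sum()) / m2**2
    num_var = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    den_var = (n - 1) * (n - 2) * (n - 3) * s0**2
    var = num_var / den_var - e_i**2
    zscore = (I - e_i) / math.sqrt(var) if var > 0 else float("nan")
    return MoranResult(I=I, expected=e_i, z=zscore, variance=var, n=n)


def gi_star(values: Grid, weights: SpatialWeights | None = None) -> HotspotMap:
    """Getis-Ord Gi* hotspot/coldspot classification of a surface.

    Each cell's z-score compares the mean of its neighbourhood (binary
    weights, self included) with the global mean; |z| crossing
    1.645/1.960/2.576 assigns the 90/95/99% class, the sign hot vs cold.
    """
    weights = weights or SpatialWeights(include_self=True)
    mask = values.valid_mask
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 valid cells")
    x = values.values[mask]
    xbar = x.mean()
    s = math.sqrt(float((x**2).mean()) - xbar**2)
    if s == 0.0:
        raise ValueError("zero variance: Gi* undefined on a constant surface")

    w = contiguity_matrix(mask, weights.scheme).astype(float)
    w = w + sparse.identity(n, format="csr")  # Gi*: the cell belongs to its own neighbourhood
    sum_wx = np.asarray(w @ x).ravel()
    sum_w = np.asarray(w.sum(axis=1)).ravel()
    sum_w2 = sum_w  # binary weights: w² = w
    denom = s * np.sqrt(np.maximum((n * sum_w2 - sum_w**2) / (n - 1), 0.0))
    zscores = np.where(denom > 0, (sum_wx - xbar * sum_w) / denom, 0.0)

    codes = np.sign(zscores) * np.searchsorted(_Z_TIERS, np.abs(zscores), side="left")
    class_grid = np.full(values.values.shape, values.nodata)
    class_grid[mask] = codes
    z_grid = np.full(values.values.shape, values.nodata)
    z_grid[mask] = zscores

    labels = [HOTSPOT_CLASSES[c] for c in sorted(HOTSPOT_CLASSES)]
    counts = pd.Series(
        [(codes == c).sum() for c in sorted(HOTSPOT_CLASSES)], index=labels, dtype=float
    )
    percents = counts / counts.sum() * 100.0
    return HotspotMap(
        classes=values.like(class_grid), z_scores=values.like(z_grid), percents=percents
    )
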