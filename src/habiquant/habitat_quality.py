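"""Habitat-quality scoring: threat kernels, degradation, quality, grades.

The model scores every cell of a categorical land-use raster in [0, 1].
Each threat r (urban land, arable land, ...) radiates from its source
cells with a distance-decay kernel — linear, ``1 − d/d_rmax``, or
exponential, ``exp(−2.99·d/d_rmax)`` — truncated at its maximum reach
d_rmax.  Degradation at cell x accumulates the decayed pressure of every
source cell of every threat, scaled by the threat's normalised weight
ω_r/Σω, the cell's accessibility β_x and the sensitivity S_jr of the
cell's own land-use class j to that threat:

    D_x = Σ_r Σ_{y ∈ sources(r)} (ω_r/Σω) · i_r(d_xy) · β_x · S_jr

Quality then discounts the class's intrinsic suitability H_j by a
saturating penalty with half-saturation constant k and exponent z:

    Q_x = H_j · (1 − D_x^z / (D_x^z + k^z))

so D = 0 gives Q = H_j and D = k halves it.  The quality surface is
finally classified into five equal-width grades and, between dates, into
improved/unchanged/degraded change maps.

Distances are centre-to-centre Euclidean, in km (cell_size is km).  The
per-threat source sum is evaluated by direct 2-D convolution of the
binary source map with the sampled decay kernel, which is exactly the
double loop over cells and sources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster_io import Grid, LandUseLegend, ThreatSpec

__all__ = [
    "HQConfig",
    "GradeTable",
    "GRADE_NAMES",
    "threat_presence",
    "decay_factor",
    "degradation",
    "quality",
    "classify_quality",
    "change_map",
]

GRADE_NAMES = ("lowest", "lower", "medium", "higher", "highest")
GRADE_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8)  # left edges of the five bins


@dataclass
class HQConfig:
    """Tunable scalars of the quality model.

    ``z`` (scaling exponent) and ``k`` (half-saturation constant) default
    to the conventional values 2.5 and 0.5.  ``beta`` is the accessibility
    level in [0, 1] — a scalar applied everywhere, or a Grid for
    spatially varying accessibility; 1 means fully accessible to threats.
    """

    z: float = 2.5
    k: float = 0.5
    beta: float | Grid = 1.0

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if isinstance(self.beta, (int, float)) and not 0.0 <= float(self.beta) <= 1.0:
            raise ValueError("beta must lie in [0,1]")

    def beta_array(self, like: Grid) -> np.ndarray:
        if isinstance(self.beta, Grid):
            if not self.beta.same_geometry(like):
                raise ValueError("beta grid geometry does not match land-use grid")
            return self.beta.values
        return np.full(like.values.shape, float(self.beta))


@dataclass
class GradeTable:
    """Percent of valid area in each of the five quality grades."""

    percents: pd.Series  # index: GRADE_NAMES

    def __post_init__(self) -> None:
        if list(self.percents.index) != list(GRADE_NAMES):
            raise ValueError(f"grade table must have rows {GRADE_NAMES}")
        if not math.isclose(float(self.percents.sum()), 100.0, abs_tol=1e-9):
            raise ValueError("grade percentages must sum to 100")


def threat_presence(lu: Grid, threat: ThreatSpec, legend: LandUseLegend | None = None) -> Grid:
    """Binary raster: 1 where the cell's class is a source of ``threat``.

    Nodata cells stay nodata; they are never sources.
    """
    if legend is not None:
        legend.check_codes(np.unique(lu.values[lu.valid_mask]).astype(int))
    valid = lu.valid_mask
    out = np.full(lu.values.shape, lu.nodata)
    codes = lu.values[valid].astype(int)
    out[valid] = np.isin(codes, list(threat.source_codes)).astype(float)
    return lu.like(out)


def decay_factor(d: float | np.ndarray, threat: ThreatSpec) -> float | np.ndarray:
    """Distance-decay weight i_r(d) in [0, 1] at distance d km.

    Linear: ``max(0, 1 − d/d_rmax)``; exponential: ``exp(−2.99·d/d_rmax)``.
    Both are truncated to 0 strictly beyond d_rmax; both equal 1 at d = 0.
    """
    arr = np.asarray(d, dtype=float)
    if (arr < 0).any():
        raise ValueError("distance must be non-negative")
    if threat.decay == "linear":
        out = np.maximum(0.0, 1.0 - arr / threat.d_rmax)
    else:
        out = np.where(arr <= threat.d_rmax, np.exp(-2.99 * arr / threat.d_rmax), 0.0)
    if np.isscalar(d):
        return float(out)
    return out


def _decay_kernel(threat: ThreatSpec, cell_size: float) -> np.ndarray:
    """The decay function sampled on the centre-offset lattice within reach."""
    radius = int(math.floor(threat.d_rmax / cell_size))
    offsets = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    dist = np.hypot(dy, dx) * cell_size
    kernel = np.asarray(decay_factor(dist, threat))
    kernel[dist > threat.d_rmax] = 0.0
    return kernel


def degradation(
    lu: Grid,
    threats: list[ThreatSpec],
    legend: LandUseLegend,
    config: HQConfig | None = None,
) -> Grid:
    """Accumulated, decayed, sensitivity-weighted threat exposure D per cell.

    Threat weights are normalised by their sum, so rescaling all ω_r by a
    common factor leaves D unchanged.  A source cell whose own class is
    sensitive to its threat is exposed at distance 0 (i = 1).
    """
    config = config or HQConfig()
    if not threats:
        raise ValueError("at least one threat is required")
    total_weight = sum(t.weight for t in threats)
    if total_weight <= 0:
        raise ValueError("threat weights sum to zero; weights cannot all vanish")

    valid = lu.valid_mask
    codes_present = np.unique(lu.values[valid]).astype(int)
    legend.check_codes(codes_present)
    beta = config.beta_array(lu)

    d = np.zeros(lu.values.shape)
    for threat in threats:
        sources = np.zeros(lu.values.shape)
        sources[valid] = np.isin(
            lu.values[valid].astype(int), list(threat.source_codes)
        ).astype(float)
        if not sources.any():
            continue
        kernel = _decay_kernel(threat, lu.cell_size)
        # direct convolution: exactly the sum over source cells within reach
        exposure = ndimage.convolve(sources, kernel, mode="constant", cval=0.0)

        sens = np.zeros(lu.values.shape)
        for code in codes_present:
            sens[valid & (lu.values == code)] = legend.sensitivity(int(code), threat.name)
        d += (threat.weight / total_weight) * exposure * sens
    d *= beta
    d[~valid] = lu.nodata
    return lu.like(d)


def quality(
    lu: Grid, d: Grid, legend: LandUseLegend, config: HQConfig | None = None
) -> Grid:
    """Quality Q = H_j · (1 − D^z/(D^z + k^z)) per cell, in [0, H_j]."""
    config = config or HQConfig()
    if not lu.same_geometry(d):
        raise ValueError("land-use and degradation grids have different geometry")
    valid = lu.valid_mask & d.valid_mask
    legend.check_codes(np.unique(lu.values[valid]).astype(int))

    h = np.zeros(lu.values.shape)
    for code in np.unique(lu.values[valid]).astype(int):
        h[valid & (lu.values == code)] = legend.suitability(int(code))

    dz = np.zeros(lu.values.shape)
    dvals = np.where(valid, d.values, 0.0)
    if (dvals < 0).any():
        raise ValueError("degradation must be non-negative")
    dz = np.power(dvals, config.z)
    q = h * (1.0 - dz / (dz + config.k**config.z))
    q[~valid] = lu.nodata
    return lu.like(q)


def classify_quality(q: Grid) -> tuple[Grid, GradeTable]:
    """Assign five grades by the bins [0,.2), [.2,.4), [.4,.6), [.6,.8), [.8,1].

    Returns the grade raster (codes 1..5, nodata preserved) and the
    percent-of-valid-area table.
    """
    valid = q.valid_mask
    vals = q.values[valid]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("quality values must lie in [0,1]")
    # digitize keeps the bin edges exact in floating point (0.6 -> "higher")
    grade_codes = np.digitize(vals, GRADE_EDGES[1:], right=False) + 1  # 1..5; 1.0 -> highest
    out = np.full(q.values.shape, q.nodata)
    out[valid] = grade_codes.astype(float)

    counts = np.bincount(grade_codes, minlength=6)[1:6]
    percents = pd.Series(counts / counts.sum() * 100.0, index=list(GRADE_NAMES))
    return q.like(out), GradeTable(percents)


def change_map(
    q_a: Grid, q_b: Grid, eps: float = 0.01
) -> tuple[Grid, pd.Series]:
    """Tri-class change raster between two quality surfaces.

    Cells improve where Q_b − Q_a > eps, degrade where < −eps, else stay
    unchanged.  Codes: +1 improved, 0 unchanged, −1 degraded.  Returns the
    raster and a percent table over cells valid at both dates.
    """
    if not q_a.same_geometry(q_b):
        raise ValueError("quality grids have different geometry")
    if eps < 0:
        raise ValueError("eps must be non-negative")
    valid = q_a.valid_mask & q_b.valid_mask
    delta = q_b.values - q_a.values
    cls = np.zeros(q_a.values.shape)
    cls[valid & (delta > eps)] = 1.0
    cls[valid & (delta < -eps)] = -1.0
    cls[~valid] = q_a.nodata

    n = valid.sum()
    table = pd.Series(
        {
            "improved": float((cls[valid] == 1).sum()) / n * 100.0,
            "unchanged": float((cls[valid] == 0).sum()) / n * 100.0,
            "degraded": float((cls[valid] == -1).sum()) / n * 100.0,
        },
        name="percent",
    )
    return q_a.like(cls), table
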