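"""Synthetic landscapes and driver data with known structure.

Every pipeline stage is testable without external rasters:

* :func:`generate_landscape_series` builds a categorical land-use raster
  with the qualitative spatial template of the study system — an eastern
  forest belt, a central cropland/urban core and a western
  grassland/saline mix — by thresholding a smoothed Gaussian noise field
  at per-zone class quantiles (a simple neutral-landscape construction),
  then evolves it by cell-independent Bernoulli conversions per step
  (the cropland-expansion dynamic).
* :class:`SemTruth` holds a fully standardized generating path model;
  :func:`generate_sem_table` draws multivariate-normal indicator data
  from its implied covariance, so estimator recovery is checkable
  against known coefficients.
* :func:`generate_covariate_stack` rasterises the same causal structure:
  smooth latent fields for topography, climate and human disturbance
  drive elevation/slope, precipitation/temperature, nightlight/population
  density and NDVI grids, with class-linked boosts (greener forest,
  brighter cities), giving the end-to-end raster→SEM pipeline a known
  signal.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster_io import Grid
from .sem_path import ParamEstimates, PathModel, default_model, implied_covariance

__all__ = [
    "LandscapeParams",
    "SemTruth",
    "BROAD_CLASS_CODES",
    "generate_landscape_series",
    "generate_sem_table",
    "generate_covariate_stack",
]

# broad synthetic classes -> representative land-use codes of the packaged legend
BROAD_CLASS_CODES = {
    "cropland": 2,   # dry farmland
    "forest": 3,     # woodland
    "grassland": 7,  # high coverage grassland
    "water": 10,     # river
    "urban": 14,     # urban area
    "saline": 18,    # saline-alkali land
    "swamp": 19,     # wetlands
}

# default class budgets: the study system's approximate year-2000 shares
_DEFAULT_PROPORTIONS = {
    "cropland": 0.59,
    "forest": 0.12,
    "grassland": 0.08,
    "water": 0.05,
    "urban": 0.045,
    "saline": 0.045,
    "swamp": 0.06,
}

# zone affinities (west, center, east) per class; rows sum to 1
_ZONE_AFFINITY = {
    "forest": (0.10, 0.10, 0.80),
    "cropland": (0.25, 0.55, 0.20),
    "urban": (0.10, 0.80, 0.10),
    "grassland": (0.70, 0.15, 0.15),
    "saline": (0.80, 0.10, 0.10),
    "swamp": (0.45, 0.25, 0.30),
    "water": (0.34, 0.33, 0.33),
}

# default cropland-expansion dynamic, per step (from_class, to_class) -> probability
_DEFAULT_CONVERSIONS = {
    ("grassland", "cropland"): 0.06,
    ("swamp", "cropland"): 0.04,
    ("forest", "cropland"): 0.015,
    ("cropland", "urban"): 0.01,
}


@dataclass
class LandscapeParams:
    """Parameters of the synthetic landscape generator."""

    nrows: int = 120
    ncols: int = 120
    cell_size: float = 1.0  # km
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    east_belt: float = 0.30     # fraction of columns forming the eastern belt
    west_belt: float = 0.30     # fraction forming the western zone
    smoothing: float = 3.0      # gaussian sigma (cells) of the patch texture
    conversion_rates: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_CONVERSIONS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid dimensions must be positive")
        total = sum(self.proportions.values())
        if any(p < 0 for p in self.proportions.values()) or total > 1 + 1e-9:
            raise ValueError("class proportions must be >= 0 and sum to <= 1")
        unknown = set(self.proportions) - set(BROAD_CLASS_CODES)
        if unknown:
            raise ValueError(f"unknown broad classes {sorted(unknown)}")
        for pair, p in self.conversion_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"conversion probability {pair} = {p} outside [0,1]")
        if not 0 < self.east_belt < 1 or not 0 < self.west_belt < 1:
            raise ValueError("belt fractions must lie in (0,1)")


def _zone_class_shares(params: LandscapeParams) -> np.ndarray:
    """Per-zone class shares whose area-weighted mix hits the global budgets.

    Iterative proportional fitting on the class x zone allocation: column
    sums match the three zone areas, row sums match the class budgets.
    """
    classes = list(params.proportions)
    props = np.array([params.proportions[c] for c in classes])
    props = props / props.sum()  # leftover mass, if any, is re-spread pro rata
    zone_frac = np.array(
        [params.west_belt, 1.0 - params.west_belt - params.east_belt, params.east_belt]
    )
    alloc = np.array([_ZONE_AFFINITY[c] for c in classes]) + 1e-3
    alloc *= props[:, None]
    for _ in range(200):
        alloc *= (props / alloc.sum(axis=1))[:, None]
        alloc *= zone_frac / alloc.sum(axis=0)
    return alloc / alloc.sum(axis=0)  # shares within each zone


def _zone_of_columns(params: LandscapeParams) -> np.ndarray:
    """0 = west, 1 = center, 2 = east per column."""
    cols = np.arange(params.ncols)
    west_end = int(round(params.west_belt * params.ncols))
    east_start = int(round((1.0 - params.east_belt) * params.ncols))
    zones = np.ones(params.ncols, dtype=int)
    zones[cols < west_end] = 0
    zones[cols >= east_start] = 2
    return zones


def _initial_landscape(params: LandscapeParams, rng: np.random.Generator) -> Grid:
    classes = list(params.proportions)
    shares = _zone_class_shares(params)  # (n_classes, 3)
    zones = _zone_of_columns(params)

    noise = rng.standard_normal((params.nrows, params.ncols))
    texture = ndimage.gaussian_filter(noise, sigma=params.smoothing)

    values = np.zeros((params.nrows, params.ncols))
    for z in range(3):
        in_zone = np.broadcast_to(zones == z, values.shape)
        cells = np.flatnonzero(in_zone.ravel())
        order = cells[np.argsort(texture.ravel()[cells], kind="stable")]
        # split the ranked cells into contiguous quantile chunks per class
        targets = np.round(np.cumsum(shares[:, z]) * len(cells)).astype(int)
        start = 0
        flat = values.ravel()
        for ci, cls in enumerate(classes):
            stop = targets[ci]
            flat[order[start:stop]] = BROAD_CLASS_CODES[cls]
            start = stop
        flat[order[start:]] = BROAD_CLASS_CODES[classes[-1]]
    return Grid(values=values, cell_size=params.cell_size)


def generate_landscape_series(params: LandscapeParams, n_dates: int) -> list[Grid]:
    """A deterministic series of categorical land-use rasters.

    Date 0 realises the east/center/west layout at the requested class
    budgets; each later date applies the per-step conversion
    probabilities cell-independently.
    """
    if n_dates < 1:
        raise ValueError("need at least one date")
    rng = np.random.default_rng(params.seed)
    series = [_initial_landscape(params, rng)]
    for _ in range(1, n_dates):
        prev = series[-1]
        nxt = prev.values.copy()
        for (src, dst), p in params.conversion_rates.items():
            if p == 0.0:
                continue
            src_code = BROAD_CLASS_CODES[src]
            dst_code = BROAD_CLASS_CODES[dst]
            here = prev.values == src_code
            flips = rng.random(prev.values.shape) < p
            nxt[here & flips] = dst_code
        series.append(prev.like(nxt))
    return series


# ---------------------------------------------------------------------------
# SEM truth and tabular data


def _solve_standardized_residuals(
    model: PathModel, paths: dict[tuple[str, str], float]
) -> dict[str, float]:
    """Residual variances making every structural node's variance exactly 1.

    Works through the nodes in topological order, accumulating the node
    covariance matrix; exogenous nodes are independent with unit variance.
    """
    import networkx as nx

    order = list(nx.topological_sort(model.graph()))
    cov = pd.DataFrame(0.0, index=order, columns=order)
    psi: dict[str, float] = {}
    for v in order:
        parents = [(s, c) for (s, t), c in paths.items() if t == v]
        if not parents:
            psi[v] = 1.0
            cov.loc[v, v] = 1.0
        else:
            names = [s for s, _ in parents]
            beta = np.array([c for _, c in parents])
            sub = cov.loc[names, names].to_numpy()
            explained = float(beta @ sub @ beta)
            if explained >= 1.0:
                raise ValueError(
                    f"node {v!r}: explained variance {explained:.3f} >= 1; "
                    "standardized coefficients too large"
                )
            psi[v] = 1.0 - explained
            for u in order:
                if u == v:
                    continue
                cov.loc[v, u] = cov.loc[u, v] = float(
                    beta @ cov.loc[names, u].to_numpy()
                )
            cov.loc[v, v] = 1.0
    return psi


@dataclass
class SemTruth:
    """A fully standardized generating path model with known coefficients."""

    model: PathModel = field(default_factory=default_model)
    loadings: dict[str, float] = field(
        default_factory=lambda: {
            "elevation": 0.90,
            "slope": 0.80,
            "precipitation": 0.85,
            "temperature": 0.75,
            "nightlight": 0.90,
            "population_density": 0.85,
        }
    )
    paths: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("Topography", "Climate"): 0.50,
            ("Topography", "HumanDisturbance"): -0.40,
            ("Topography", "NDVI"): 0.45,
            ("Topography", "HQ"): 0.25,
            ("Climate", "NDVI"): 0.20,
            ("Climate", "HQ"): 0.20,
            ("HumanDisturbance", "NDVI"): -0.30,
            ("HumanDisturbance", "HQ"): -0.30,
            ("NDVI", "HQ"): 0.25,
        }
    )
    n: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for ind, lam in self.loadings.items():
            if not 0.0 < abs(lam) <= 1.0:
                raise ValueError(f"standardized loading for {ind!r} must be in (0,1]")
        sigma = self.implied_cov()
        if np.linalg.eigvalsh(sigma).min() <= 0:
            raise ValueError("truth's implied covariance is not positive-definite")

    def params(self) -> ParamEstimates:
        """The truth as a (standardized = unstandardized) parameter set."""
        psi = _solve_standardized_residuals(self.model, self.paths)
        theta = {ind: 1.0 - lam**2 for ind, lam in self.loadings.items()}
        return ParamEstimates(
            loadings=dict(self.loadings),
            structural=dict(self.paths),
            psi=psi,
            theta=theta,
            standardized_loadings=dict(self.loadings),
            standardized_paths=dict(self.paths),
        )

    def implied_cov(self) -> np.ndarray:
        return implied_covariance(self.model, self.params())


def generate_sem_table(truth: SemTruth) -> pd.DataFrame:
    """Multivariate-normal indicator table drawn from the truth's covariance."""
    sigma = truth.implied_cov()
    chol = np.linalg.cholesky(sigma)
    rng = np.random.default_rng(truth.seed)
    z = rng.standard_normal((truth.n, sigma.shape[0]))
    return pd.DataFrame(z @ chol.T, columns=truth.model.observed)


# ---------------------------------------------------------------------------
# Covariate rasters


def _smooth_unit_field(
    shape: tuple[int, int], rng: np.random.Generator, sigma: float = 6.0
) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return (f - f.mean()) / f.std()


def generate_covariate_stack(
    landscape: Grid, truth: SemTruth | None = None, seed: int = 0
) -> dict[str, Grid]:
    """Driver covariate rasters causally linked per the truth's graph.

    Latent fields: topography rises eastwards (matching the forest
    belt); climate and human disturbance respond to topography with the
    truth's structural coefficients; NDVI responds to all three plus a
    land-class boost (forest green, urban grey); the observed rasters
    are noisy indicator versions.  Deterministic given the seed.
    """
    truth = truth or SemTruth()
    rng = np.random.default_rng(seed)
    shape = landscape.values.shape
    lu = landscape.values

    cols = np.linspace(-1.0, 1.0, shape[1])
    gradient = np.broadcast_to(cols, shape)
    topo = 0.8 * gradient + 0.6 * _smooth_unit_field(shape, rng)
    topo = (topo - topo.mean()) / topo.std()

    def child(coefs: dict[str, float], parents: dict[str, np.ndarray]) -> np.ndarray:
        f = sum(c * parents[p] for p, c in coefs.items())
        explained = float(np.var(f))
        resid = max(1.0 - min(explained, 0.99), 0.01)
        f = f + math.sqrt(resid) * _smooth_unit_field(shape, rng)
        return (f - f.mean()) / f.std()

    p = truth.paths
    climate = child({"Topography": p[("Topography", "Climate")]}, {"Topography": topo})
    urban_mask = (lu == 14) | (lu == 15)
    hd_base = child(
        {"Topography": p[("Topography", "HumanDisturbance")]}, {"Topography": topo}
    )
    hd = hd_base + 1.5 * ndimage.gaussian_filter(urban_mask.astype(float), sigma=3.0)
    hd = (hd - hd.mean()) / hd.std()

    greenness = np.zeros(shape)
    greenness[lu == 3] = 1.0   # woodland
    greenness[lu == 7] = 0.5   # grassland
    greenness[lu == 19] = 0.4  # wetlands
    greenness[urban_mask] = -1.0
    ndvi = child(
        {
            "Topography": p[("Topography", "NDVI")],
            "Climate": p[("Climate", "NDVI")],
            "HumanDisturbance": p[("HumanDisturbance", "NDVI")],
        },
        {"Topography": topo, "Climate": climate, "HumanDisturbance": hd},
    )
    # the class boost shifts the level and is deliberately not re-centred,
    # so all-forest and all-urban landscapes differ in mean greenness
    ndvi = ndvi + 0.8 * ndimage.gaussian_filter(greenness, sigma=2.0)

    def indicator(latent: np.ndarray, name: str) -> np.ndarray:
        lam = truth.loadings[name]
        noise = rng.standard_normal(shape) * np.sqrt(max(1.0 - lam**2, 1e-6))
        return lam * latent + noise

    stack = {
        "elevation": indicator(topo, "elevation"),
        "slope": indicator(topo, "slope"),
        "precipitation": indicator(climate, "precipitation"),
        "temperature": indicator(climate, "temperature"),
        "nightlight": indicator(hd, "nightlight"),
        "population_density": indicator(hd, "population_density"),
        "NDVI": ndvi,
    }
    return {name: landscape.like(arr) for name, arr in stack.items()}
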