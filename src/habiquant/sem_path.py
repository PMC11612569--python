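"""Latent-variable path modelling of habitat-quality drivers.

A covariance-based structural equation model in the all-y LISREL form:
observed indicators load on latent constructs through the measurement
model ``Y = Λ η + ε``, and the constructs (plus directly observed
structural nodes such as NDVI and the quality score itself) are linked
by the structural model ``η = B η + ζ``.  The implied covariance is

    Σ(θ) = Λ (I − B)⁻¹ Ψ (I − B)⁻ᵀ Λᵀ + Θ

and parameters are estimated by minimising the maximum-likelihood
discrepancy ``F = log|Σ| + tr(S Σ⁻¹) − log|S| − p`` against the sample
covariance S.  Identification fixes the first loading of every latent to
1; the standardized solution is derived afterwards from the implied
variances.  Fit is summarised by χ², CFI, GFI, RMSEA and SRMR.

Because the structural graph is acyclic, the effect of a driver on a
response decomposes exactly into the direct edge coefficient plus one
product of standardized coefficients per directed path — the classical
direct/indirect/total decomposition of path analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PathModel",
    "ParamEstimates",
    "FitIndices",
    "EffectRow",
    "rank_normalize",
    "implied_covariance",
    "fit_ml",
    "effect_decomposition",
    "total_effects_matrix",
    "default_model",
    "load_reported_path_coefficients",
    "structural_model_from_paths",
]


# ---------------------------------------------------------------------------
# Model structure


@dataclass
class PathModel:
    """Measurement structure and directed structural paths.

    ``latents`` maps each construct to its ≥2 indicators (each indicator
    loads on exactly one construct); ``observed_structural`` lists nodes
    that enter the structural model directly as observed variables;
    ``paths`` are directed edges among structural nodes.  The structural
    graph must be acyclic, and a node named ``HQ`` (the response) may
    have no outgoing edges.
    """

    latents: dict[str, list[str]] = field(default_factory=dict)
    observed_structural: list[str] = field(default_factory=list)
    paths: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.paths = [tuple(p) for p in self.paths]
        seen: dict[str, str] = {}
        for latent, indicators in self.latents.items():
            if len(indicators) < 2:
                raise ValueError(f"latent {latent!r} needs at least 2 indicators")
            for ind in indicators:
                if ind in seen:
                    raise ValueError(f"indicator {ind!r} loads on both {seen[ind]!r} and {latent!r}")
                seen[ind] = latent
        nodes = set(self.structural_nodes)
        for s, t in self.paths:
            if s not in nodes or t not in nodes:
                raise ValueError(f"path {s}->{t} references unknown structural node")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("structural graph must be acyclic")
        if "HQ" in nodes and any(s == "HQ" for s, _ in self.paths):
            raise ValueError("HQ is the response and may have no outgoing paths")

    @property
    def structural_nodes(self) -> list[str]:
        return list(self.latents) + list(self.observed_structural)

    @property
    def observed(self) -> list[str]:
        """All observed variables, indicators first, in model order."""
        out: list[str] = []
        for indicators in self.latents.values():
            out.extend(indicators)
        out.extend(self.observed_structural)
        return out

    @property
    def exogenous(self) -> list[str]:
        targets = {t for _, t in self.paths}
        return [v for v in self.structural_nodes if v not in targets]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.structural_nodes)
        g.add_edges_from(self.paths)
        return g

    @classmethod
    def from_dict(cls, spec: dict) -> "PathModel":
        return cls(
            latents={k: list(v) for k, v in spec.get("latents", {}).items()},
            observed_structural=list(spec.get("observed", [])),
            paths=[tuple(p) for p in spec.get("paths", [])],
        )


def default_model() -> PathModel:
    """The driver model: topography, climate and human disturbance as
    latent constructs, NDVI as observed mediator, HQ as response."""
    return PathModel(
        latents={
            "Topography": ["elevation", "slope"],
            "Climate": ["precipitation", "temperature"],
            "HumanDisturbance": ["nightlight", "population_density"],
        },
        observed_structural=["NDVI", "HQ"],
        paths=[
            ("Topography", "Climate"),
            ("Topography", "HumanDisturbance"),
            ("Topography", "NDVI"),
            ("Topography", "HQ"),
            ("Climate", "NDVI"),
            ("Climate", "HQ"),
            ("HumanDisturbance", "NDVI"),
            ("HumanDisturbance", "HQ"),
            ("NDVI", "HQ"),
        ],
    )


@dataclass
class ParamEstimates:
    """Model parameters: unstandardized and (if derived) standardized."""

    loadings: dict[str, float]  # indicator -> λ (first per latent is 1)
    structural: dict[tuple[str, str], float]  # (src, dst) -> coefficient
    psi: dict[str, float]  # structural-node residual/exogenous variance
    theta: dict[str, float]  # indicator measurement-error variance
    standardized_loadings: dict[str, float] = field(default_factory=dict)
    standardized_paths: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class FitIndices:
    chi2: float
    df: int
    cfi: float
    gfi: float
    rmsea: float
    srmr: float

    def passes_gates(self) -> bool:
        """The conventional acceptance gates: CFI, GFI > 0.90; RMSEA < 0.06; SRMR < 0.05."""
        return self.cfi > 0.90 and self.gfi > 0.90 and self.rmsea < 0.06 and self.srmr < 0.05


@dataclass
class EffectRow:
    """Direct/indirect/total standardized effects of one driver."""

    driver: str
    response: str
    direct: float
    indirect: list[tuple[str, float]]  # (path label, product of coefficients)

    @property
    def indirect_total(self) -> float:
        return float(sum(v for _, v in self.indirect))

    @property
    def total(self) -> float:
        return self.direct + self.indirect_total


# ---------------------------------------------------------------------------
# Normalisation


def rank_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform followed by z-standardisation.

    Maps ranks through Φ⁻¹((r − 3/8)/(n + 1/4)); monotone in the input,
    output mean 0 and sd 1.  Used to normalise skewed driver variables
    before covariance modelling.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if x.size < 3 or not np.isfinite(x).all():
        raise ValueError("need at least 3 finite values")
    if np.all(x == x[0]):
        raise ValueError("all values tied: transform undefined")
    ranks = stats.rankdata(x, method="average")
    n = x.size
    z = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return (z - z.mean()) / z.std()


# ---------------------------------------------------------------------------
# Implied covariance


def _matrices(model: PathModel, params: ParamEstimates):
    nodes = model.structural_nodes
    obs = model.observed
    m, p = len(nodes), len(obs)
    node_ix = {v: i for i, v in enumerate(nodes)}
    obs_ix = {v: i for i, v in enumerate(obs)}

    lam = np.zeros((p, m))
    theta = np.zeros(p)
    for latent, indicators in model.latents.items():
        for ind in indicators:
            lam[obs_ix[ind], node_ix[latent]] = params.loadings.get(ind, 1.0)
            theta[obs_ix[ind]] = params.theta.get(ind, 0.0)
    for v in model.observed_structural:
        lam[obs_ix[v], node_ix[v]] = 1.0  # observed node is its own construct

    b = np.zeros((m, m))
    for (s, t), coef in params.structural.items():
        b[node_ix[t], node_ix[s]] = coef
    psi = np.diag([params.psi.get(v, 1.0) for v in nodes])
    return lam, b, psi, np.diag(theta)


def latent_covariance(model: PathModel, params: ParamEstimates) -> np.ndarray:
    """Model-implied covariance of the structural nodes, (I−B)⁻¹Ψ(I−B)⁻ᵀ."""
    _, b, psi, _ = _matrices(model, params)
    m = b.shape[0]
    a = np.linalg.solve(np.eye(m) - b, np.eye(m))
    return a @ psi @ a.T


def implied_covariance(model: PathModel, params: ParamEstimates) -> np.ndarray:
    """Model-implied covariance Σ(θ) over the observed variables.

    Raises if (I − B) is singular; the result is symmetric PSD for
    admissible parameters.
    """
    lam, b, psi, theta = _matrices(model, params)
    m = b.shape[0]
    i_b = np.eye(m) - b
    if abs(np.linalg.det(i_b)) < 1e-12:
        raise np.linalg.LinAlgError("(I - B) is singular")
    a = np.linalg.solve(i_b, np.eye(m))
    sigma_eta = a @ psi @ a.T
    sigma = lam @ sigma_eta @ lam.T + theta
    return (sigma + sigma.T) / 2.0


# ---------------------------------------------------------------------------
# ML estimation


def _free_parameters(model: PathModel, sample_var: dict[str, float]):
    """Free-parameter labels, start values and bounds.

    First loading per latent fixed to 1; measurement residuals free for
    real indicators; structural-node variances free.
    """
    labels: list[tuple[str, ...]] = []
    starts: list[float] = []
    bounds: list[tuple[float | None, float | None]] = []

    for latent, indicators in model.latents.items():
        for ind in indicators[1:]:
            labels.append(("loading", ind))
            starts.append(1.0)
            bounds.append((None, None))
    for s, t in model.paths:
        labels.append(("path", s, t))
        starts.append(0.0)
        bounds.append((None, None))
    for v in model.structural_nodes:
        labels.append(("psi", v))
        if v in model.latents:
            anchor = model.latents[v][0]
            starts.append(0.5 * sample_var.get(anchor, 1.0))
        else:
            starts.append(0.5 * sample_var.get(v, 1.0))
        bounds.append((1e-6, None))
    for latent, indicators in model.latents.items():
        for ind in indicators:
            labels.append(("theta", ind))
            starts.append(0.5 * sample_var.get(ind, 1.0))
            bounds.append((1e-6, None))
    return labels, np.array(starts), bounds


def _unpack(labels, vector) -> ParamEstimates:
    loadings: dict[str, float] = {}
    structural: dict[tuple[str, str], float] = {}
    psi: dict[str, float] = {}
    theta: dict[str, float] = {}
    for label, value in zip(labels, vector):
        kind = label[0]
        if kind == "loading":
            loadings[label[1]] = value
        elif kind == "path":
            structural[(label[1], label[2])] = value
        elif kind == "psi":
            psi[label[1]] = value
        elif kind == "theta":
            theta[label[1]] = value
    return ParamEstimates(loadings=loadings, structural=structural, psi=psi, theta=theta)


def _ml_discrepancy(sigma: np.ndarray, s: np.ndarray, logdet_s: float) -> float:
    p = s.shape[0]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10
    try:
        sinv_s = np.linalg.solve(sigma, s)
    except np.linalg.LinAlgError:
        return 1e10
    return float(logdet + np.trace(sinv_s) - logdet_s - p)


def fit_ml(
    sample_cov: np.ndarray | pd.DataFrame,
    n: int,
    model: PathModel,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-8,
) -> tuple[ParamEstimates, FitIndices]:
    """Fit the model to a sample covariance by maximum likelihood.

    ``sample_cov`` may be a DataFrame (reordered to the model's observed
    order) or an array already in that order.  Optimisation is L-BFGS-B
    with up to ``n_restarts`` seeded jittered restarts; raises if no start
    converges.  Returns estimates (with the standardized solution filled
    in) and fit indices.
    """
    obs = model.observed
    p = len(obs)
    if isinstance(sample_cov, pd.DataFrame):
        missing = [v for v in obs if v not in sample_cov.columns]
        if missing:
            raise ValueError(f"sample covariance lacks variables {missing}")
        s = sample_cov.loc[obs, obs].to_numpy(dtype=float)
    else:
        s = np.asarray(sample_cov, dtype=float)
        if s.shape != (p, p):
            raise ValueError(f"sample covariance must be {p}x{p} in observed order {obs}")
    s = (s + s.T) / 2.0
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("sample covariance must be positive-definite")
    if n <= p:
        raise ValueError("sample size must exceed the number of observed variables")

    sample_var = {v: float(s[i, i]) for i, v in enumerate(obs)}
    labels, starts, bounds = _free_parameters(model, sample_var)

    def objective(vec: np.ndarray) -> float:
        params = _unpack(labels, vec)
        try:
            sigma = implied_covariance(model, params)
        except np.linalg.LinAlgError:
            return 1e10
        return _ml_discrepancy(sigma, s, logdet_s)

    rng = np.random.default_rng(seed)
    best = None
    f0 = objective(starts)
    for attempt in range(n_restarts):
        x0 = starts if attempt == 0 else starts + rng.normal(0.0, 0.1, size=starts.size)
        x0 = np.clip(x0, [b[0] if b[0] is not None else -np.inf for b in bounds], np.inf)
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": tol, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.success and best.fun < f0:
            break
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e9:
        raise RuntimeError(
            f"ML estimation did not converge; best discrepancy {None if best is None else best.fun}"
        )

    params = _unpack(labels, best.x)
    _standardize(model, params)
    fit = _fit_indices(model, params, s, n, logdet_s, n_free=len(labels))
    return params, fit


def _standardize(model: PathModel, params: ParamEstimates) -> None:
    """Fill in standardized loadings and path coefficients in place."""
    nodes = model.structural_nodes
    sigma_eta = latent_covariance(model, params)
    sd_eta = {v: math.sqrt(max(sigma_eta[i, i], 0.0)) for i, v in enumerate(nodes)}
    sigma = implied_covariance(model, params)
    obs = model.observed
    sd_obs = {v: math.sqrt(max(sigma[i, i], 0.0)) for i, v in enumerate(obs)}

    for latent, indicators in model.latents.items():
        for ind in indicators:
            lam = params.loadings.get(ind, 1.0)
            if sd_obs[ind] > 0:
                params.standardized_loadings[ind] = lam * sd_eta[latent] / sd_obs[ind]
    for (src, dst), coef in params.structural.items():
        if sd_eta[dst] > 0:
            params.standardized_paths[(src, dst)] = coef * sd_eta[src] / sd_eta[dst]


def _fit_indices(
    model: PathModel,
    params: ParamEstimates,
    s: np.ndarray,
    n: int,
    logdet_s: float,
    n_free: int,
) -> FitIndices:
    p = s.shape[0]
    sigma = implied_covariance(model, params)
    f = _ml_discrepancy(sigma, s, logdet_s)
    chi2 = (n - 1) * f
    df = p * (p + 1) // 2 - n_free

    # independence baseline: Sigma_b = diag(S)
    f_b = float(np.log(np.diag(s)).sum() - logdet_s)
    chi2_b = (n - 1) * f_b
    df_b = p * (p - 1) // 2

    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 1e-12)
    cfi = 1.0 - num / den
    sinv_s = np.linalg.solve(sigma, s)
    resid = sinv_s - np.eye(p)
    gfi = 1.0 - np.trace(resid @ resid) / np.trace(sinv_s @ sinv_s)
    rmsea = math.sqrt(num / (df * (n - 1))) if df > 0 else 0.0

    d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    std_resid = (s - sigma) / d
    iu = np.triu_indices(p)
    srmr = math.sqrt(float((std_resid[iu] ** 2).mean()))
    return FitIndices(chi2=chi2, df=df, cfi=cfi, gfi=gfi, rmsea=rmsea, srmr=srmr)


# ---------------------------------------------------------------------------
# Effect decomposition


def effect_decomposition(
    model: PathModel,
    standardized: ParamEstimates | dict[tuple[str, str], float],
    driver: str,
    response: str = "HQ",
) -> EffectRow:
    """Direct, indirect and total standardized effects of ``driver``.

    The direct effect is the coefficient on the edge driver→response (0
    if absent); each indirect contribution is the product of standardized
    coefficients along one simple directed path of length ≥ 2; the total
    is their sum.  Path enumeration is exhaustive — the structural graph
    is acyclic.
    """
    coefs = (
        standardized.standardized_paths
        if isinstance(standardized, ParamEstimates)
        else dict(standardized)
    )
    g = nx.DiGraph()
    g.add_nodes_from(model.structural_nodes)
    for (s, t) in model.paths:
        g.add_edge(s, t, coef=coefs.get((s, t), 0.0))
    if driver not in g or response not in g:
        raise ValueError(f"unknown node: {driver!r} or {response!r}")

    direct = coefs.get((driver, response), 0.0)
    indirect: list[tuple[str, float]] = []
    for path in nx.all_simple_paths(g, driver, response):
        if len(path) == 2:
            continue
        product = 1.0
        for a, b in zip(path, path[1:]):
            product *= g.edges[a, b]["coef"]
        indirect.append((" -> ".join(path), product))
    return EffectRow(driver=driver, response=response, direct=direct, indirect=indirect)


def load_reported_path_coefficients() -> dict[int, dict[tuple[str, str], float]]:
    """The packaged per-year standardized path coefficients of the driver
    models (one edge set per study year), keyed by year."""
    from importlib import resources

    path = resources.files("habiquant") / "data" / "path_coefficients.csv"
    df = pd.read_csv(str(path))
    out: dict[int, dict[tuple[str, str], float]] = {}
    for year, grp in df.groupby("year"):
        out[int(year)] = {
            (row["src"], row["dst"]): float(row["coefficient"]) for _, row in grp.iterrows()
        }
    return out


def structural_model_from_paths(
    coefs: dict[tuple[str, str], float]
) -> PathModel:
    """A structural-only model (no measurement part) over the edge set."""
    nodes: list[str] = []
    for s, t in coefs:
        for v in (s, t):
            if v not in nodes:
                nodes.append(v)
    return PathModel(latents={}, observed_structural=nodes, paths=list(coefs))


def total_effects_matrix(
    model: PathModel, standardized: ParamEstimates | dict[tuple[str, str], float]
) -> pd.DataFrame:
    """Reduced-form total effects (I − B)⁻¹ − I over structural nodes.

    Independent of the path-enumeration route: for an acyclic graph the
    Neumann series Σ_{k≥1} Bᵏ terminates and its (t, s) entry is the
    total effect of s on t.
    """
    coefs = (
        standardized.standardized_paths
        if isinstance(standardized, ParamEstimates)
        else dict(standardized)
    )
    nodes = model.structural_nodes
    ix = {v: i for i, v in enumerate(nodes)}
    m = len(nodes)
    b = np.zeros((m, m))
    for (s, t) in model.paths:
        b[ix[t], ix[s]] = coefs.get((s, t), 0.0)
    total = np.linalg.solve(np.eye(m) - b, np.eye(m)) - np.eye(m)
    return pd.DataFrame(total, index=nodes, columns=nodes)
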