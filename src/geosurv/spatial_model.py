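"""Bayesian geostatistical Weibull PH model with spatially varying effects.

The mortality hazard of child j in cluster s_i of region q(i) is

    h(t) = δ t^{δ-1} exp( βᵀX_j + (a + w_{q(i)}) Z_{q(i)} + φ(s_i) )

where Z is the regional coverage of one intervention, ``a`` its national
log-hazard-ratio per coverage unit, ``w`` proper-CAR regional deviations from
``a``, and φ a Gaussian-process cluster frailty with exponential correlogram
exp(−dρ). Priors: σ², σq² ~ IG(2.01, 1.01); ρ uniform with the effective
range −log(0.05)/ρ constrained between the smallest and largest observed
inter-cluster distances; γ uniform over the interval keeping (I − γC)⁻¹D
positive definite; δ ~ Exponential(0.01); β, a ~ N(0, 10³).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import survival_core
from .data_model import RegionGraph, SpatialFrame, ValidationError

#: −log(0.05): correlation exp(−dρ) falls to 0.05 at d = EFFECTIVE_RANGE_FACTOR / ρ.
EFFECTIVE_RANGE_FACTOR = -np.log(0.05)

COVERAGE_UNITS = {
    "per10pp": 10.0,     # Z = proportion / 0.10 (ten percentage points per unit)
    "proportion": 1.0,
    "percent": 100.0,
}


def scale_coverage(proportion, unit: str = "per10pp"):
    """Express coverage proportions in the regression unit for Z."""
    try:
        factor = COVERAGE_UNITS[unit]
    except KeyError:
        raise ValueError(f"unknown coverage unit {unit!r}; choose from {sorted(COVERAGE_UNITS)}")
    return np.asarray(proportion, dtype=float) * factor


# ---------------------------------------------------------------------------
# covariance building blocks
# ---------------------------------------------------------------------------

def gp_covariance(distances, sigma2: float, rho: float, jitter: float = 1e-8) -> np.ndarray:
    """σ² exp(−dρ) with a relative diagonal jitter for numerical stability."""
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if sigma2 <= 0 or rho <= 0:
        raise ValueError("sigma2 and rho must be positive")
    cov = sigma2 * np.exp(-d * rho)
    cov[np.diag_indices_from(cov)] += jitter * sigma2
    return cov


def effective_range(rho):
    """Distance at which the exponential correlation drops to 0.05."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be positive")
    return EFFECTIVE_RANGE_FACTOR / rho


def rho_bounds(distances) -> tuple[float, float]:
    """Support (a, b) of the uniform prior on the GP decay rate ρ.

    Chosen so the effective range −log(0.05)/ρ lies between the largest and
    the smallest nonzero inter-point distance: a = −log(0.05)/d_max,
    b = −log(0.05)/d_min⁺.
    """
    d = np.asarray(distances, dtype=float)
    off = d[np.triu_indices_from(d, k=1)]
    positive = off[off > 0]
    if positive.size == 0:
        raise ValidationError("all locations coincide; rho prior undefined")
    return (EFFECTIVE_RANGE_FACTOR / positive.max(), EFFECTIVE_RANGE_FACTOR / positive.min())


def car_covariance(region_graph: RegionGraph, sigmaq2: float, gamma: float) -> np.ndarray:
    """Proper-CAR covariance σq² (I − γC)⁻¹ D; symmetric positive definite."""
    lo, hi = region_graph.gamma_bounds
    if not (lo < gamma < hi):
        raise ValueError(f"gamma={gamma} outside the admissible open interval ({lo}, {hi})")
    if sigmaq2 <= 0:
        raise ValueError("sigmaq2 must be positive")
    Q = region_graph.n_regions
    cov = sigmaq2 * np.linalg.solve(np.eye(Q) - gamma * region_graph.C, region_graph.D)
    return 0.5 * (cov + cov.T)


def car_precision(region_graph: RegionGraph, sigmaq2: float, gamma: float) -> np.ndarray:
    """Inverse of :func:`car_covariance`: (diag(g) − γω) / σq²."""
    return (np.diag(region_graph.g) - gamma * region_graph.omega) / sigmaq2


def car_logpdf(w, region_graph: RegionGraph, sigmaq2: float, gamma: float) -> float:
    """Log-density of the proper-CAR prior, via the eigenvalues of C.

    log|Σ| = Q log σq² − Σ_k log g_k − Σ_i log(1 − γλ_i) with λ_i the (real)
    eigenvalues of D^{-1/2} C D^{1/2}.
    """
    w = np.asarray(w, dtype=float)
    Q = region_graph.n_regions
    lam = region_graph.car_eigenvalues
    logdet = Q * np.log(sigmaq2) - np.sum(np.log(region_graph.g)) - np.sum(np.log1p(-gamma * lam))
    quad = float(w @ car_precision(region_graph, sigmaq2, gamma) @ w)
    return -0.5 * (Q * np.log(2.0 * np.pi) + logdet + quad)


def chol_with_jitter(cov: np.ndarray, max_tries: int = 6):
    """Cholesky factor with escalating diagonal jitter; raises after max_tries."""
    scale = float(np.mean(np.diag(cov)))
    jitter = 0.0
    for k in range(max_tries):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0])), jitter
        except np.linalg.LinAlgError:
            jitter = scale * 10.0 ** (-8 + 2 * k)
    raise np.linalg.LinAlgError("covariance not positive definite after jitter escalation")


def mvn_logpdf_chol(x, cov) -> float:
    from scipy.linalg import solve_triangular

    L, _ = chol_with_jitter(np.asarray(cov, dtype=float))
    u = solve_triangular(L, np.asarray(x, dtype=float), lower=True)
    return float(-0.5 * (len(u) * np.log(2.0 * np.pi) + u @ u) - np.sum(np.log(np.diag(L))))


# ---------------------------------------------------------------------------
# priors and model assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the model priors."""

    ig_shape: float = 2.01
    ig_scale: float = 1.01
    delta_rate: float = 0.01
    coef_variance: float = 1e3
    rho_support: tuple[float, float] | None = None     # filled from the data
    gamma_support: tuple[float, float] | None = None   # filled from the graph

    def with_supports(self, distances, region_graph: RegionGraph) -> "PriorSpec":
        return replace(
            self,
            rho_support=rho_bounds(distances),
            gamma_support=region_graph.gamma_bounds,
        )


@dataclass(frozen=True)
class ModelSpec:
    """Which intervention and adjustment covariates enter one model fit."""

    intervention: str
    covariates: tuple[str, ...] = ()
    coverage_unit: str = "per10pp"
    priors: PriorSpec = field(default_factory=PriorSpec)


@dataclass
class ModelState:
    """One point in parameter space: all unknowns of the hierarchical model."""

    delta: float
    beta: np.ndarray
    a: float
    w: np.ndarray
    phi: np.ndarray
    sigma2: float
    rho: float
    sigmaq2: float
    gamma: float

    def copy(self) -> "ModelState":
        return ModelState(
            self.delta, self.beta.copy(), self.a, self.w.copy(), self.phi.copy(),
            self.sigma2, self.rho, self.sigmaq2, self.gamma,
        )


@dataclass
class ModelData:
    """Pre-assembled arrays for likelihood evaluation.

    ``X`` includes a leading intercept column; ``Z`` is the per-child regional
    coverage on the regression scale; ``child_cluster`` and ``cluster_region``
    are integer index maps.
    """

    times: np.ndarray
    events: np.ndarray
    X: np.ndarray
    column_names: list
    Z: np.ndarray
    child_cluster: np.ndarray
    cluster_region: np.ndarray
    distances: np.ndarray
    region_graph: RegionGraph
    priors: PriorSpec
    spec: ModelSpec
    region_Z: np.ndarray = None  # coverage per region on the regression scale
    n_time_shifted: int = 0

    @property
    def n_children(self) -> int:
        return len(self.times)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_region)

    @property
    def n_regions(self) -> int:
        return self.region_graph.n_regions

    def eta(self, state: ModelState) -> np.ndarray:
        w_child = state.w[self.cluster_region[self.child_cluster]]
        return (
            self.X @ state.beta
            + (state.a + w_child) * self.Z
            + state.phi[self.child_cluster]
        )

    def initial_state(self, rng: np.random.Generator | None = None) -> ModelState:
        """Default initialisation; with ``rng`` given, jittered by N(0, 0.1²)."""
        lo_r, hi_r = self.priors.rho_support
        lo_g, hi_g = self.priors.gamma_support
        state = ModelState(
            delta=1.0,
            beta=np.zeros(self.X.shape[1]),
            a=0.0,
            w=np.zeros(self.n_regions),
            phi=np.zeros(self.n_clusters),
            sigma2=0.5,
            rho=0.5 * (lo_r + hi_r),
            sigmaq2=0.5,
            gamma=0.0,
        )
        if rng is not None:
            j = 0.1
            state.delta = float(np.exp(np.log(state.delta) + j * rng.standard_normal()))
            state.beta = state.beta + j * rng.standard_normal(state.beta.shape)
            state.a += j * rng.standard_normal()
            state.w = state.w + j * rng.standard_normal(state.w.shape)
            state.phi = state.phi + j * rng.standard_normal(state.phi.shape)
            state.sigma2 = float(np.exp(np.log(state.sigma2) + j * rng.standard_normal()))
            state.sigmaq2 = float(np.exp(np.log(state.sigmaq2) + j * rng.standard_normal()))
            width = hi_r - lo_r
            state.rho = float(np.clip(state.rho + 0.05 * width * rng.standard_normal(),
                                      lo_r + 1e-9 * width, hi_r - 1e-9 * width))
            gwidth = hi_g - lo_g
            state.gamma = float(np.clip(state.gamma + 0.05 * gwidth * rng.standard_normal(),
                                        lo_g + 1e-9 * gwidth, hi_g - 1e-9 * gwidth))
        return state


def build_model(children, spatial_frame: SpatialFrame, region_graph: RegionGraph,
                coverage, spec: ModelSpec) -> ModelData:
    """Assemble a :class:`ModelData` from validated survey tables.

    ``coverage`` is the region × intervention proportion table; the chosen
    intervention column is mapped onto children through their cluster's
    region and rescaled to the configured coverage unit.
    """
    from .screening import build_design  # local import to avoid a cycle

    if spec.intervention not in coverage.columns:
        raise ValidationError(f"intervention {spec.intervention!r} not in coverage table")
    cluster_index = {c: i for i, c in enumerate(spatial_frame.cluster_ids)}
    child_cluster = children["cluster_id"].map(cluster_index)
    if child_cluster.isna().any():
        raise ValidationError("children reference clusters absent from the spatial frame")
    child_cluster = child_cluster.to_numpy(dtype=int)
    cluster_region = spatial_frame.region_index(region_graph.region_ids)

    region_Z = scale_coverage(
        coverage[spec.intervention].reindex(region_graph.region_ids).to_numpy(),
        spec.coverage_unit,
    )
    if np.any(np.isnan(region_Z)):
        raise ValidationError("coverage table missing regions present in the graph")
    Z = region_Z[cluster_region[child_cluster]]

    X, names = build_design(children, spec.covariates)
    times, n_shifted = survival_core.shift_zero_times(children["time_months"].to_numpy())
    return ModelData(
        times=times,
        events=children["event"].to_numpy(dtype=float),
        X=X,
        column_names=names,
        Z=Z,
        child_cluster=child_cluster,
        cluster_region=cluster_region,
        distances=spatial_frame.distances,
        region_graph=region_graph,
        priors=spec.priors.with_supports(spatial_frame.distances, region_graph),
        spec=spec,
        region_Z=region_Z,
        n_time_shifted=n_shifted,
    )


def prior_model(region_graph: RegionGraph, priors: PriorSpec | None = None,
                rho_support: tuple[float, float] = (0.05, 1.0)) -> ModelData:
    """A data-free model (no children, no clusters) whose posterior is the prior.

    Useful to exercise the sampler against known prior moments; the latent
    cluster field is absent, so σ² and ρ are targeted by their priors alone.
    """
    priors = priors or PriorSpec()
    priors = replace(priors, rho_support=rho_support, gamma_support=region_graph.gamma_bounds)
    return ModelData(
        times=np.empty(0),
        events=np.empty(0),
        X=np.empty((0, 1)),
        column_names=["intercept"],
        Z=np.empty(0),
        child_cluster=np.empty(0, dtype=int),
        cluster_region=np.empty(0, dtype=int),
        distances=np.empty((0, 0)),
        region_graph=region_graph,
        priors=priors,
        spec=ModelSpec(intervention="none", priors=priors),
        region_Z=np.zeros(region_graph.n_regions),
    )


# ---------------------------------------------------------------------------
# log posterior
# ---------------------------------------------------------------------------

def in_support(state: ModelState, priors: PriorSpec) -> bool:
    lo_r, hi_r = priors.rho_support
    lo_g, hi_g = priors.gamma_support
    return (
        state.delta > 0
        and state.sigma2 > 0
        and state.sigmaq2 > 0
        and lo_r <= state.rho <= hi_r
        and lo_g < state.gamma < hi_g
        and np.all(np.isfinite(state.beta))
        and np.isfinite(state.a)
    )


def log_prior(state: ModelState, priors: PriorSpec) -> float:
    lo_r, hi_r = priors.rho_support
    lo_g, hi_g = priors.gamma_support
    ig = stats.invgamma(priors.ig_shape, scale=priors.ig_scale)
    coef_sd = np.sqrt(priors.coef_variance)
    lp = ig.logpdf(state.sigma2) + ig.logpdf(state.sigmaq2)
    lp += stats.expon.logpdf(state.delta, scale=1.0 / priors.delta_rate)
    lp += float(np.sum(stats.norm.logpdf(state.beta, scale=coef_sd)))
    lp += stats.norm.logpdf(state.a, scale=coef_sd)
    lp += -np.log(hi_r - lo_r) - np.log(hi_g - lo_g)
    return float(lp)


def log_posterior_parts(state: ModelState, data: ModelData) -> dict:
    """The four additive components of the (unnormalised) log posterior."""
    if not in_support(state, data.priors):
        return {"survival": -np.inf, "gp": -np.inf, "car": -np.inf, "prior": -np.inf}
    parts = {}
    if data.n_children:
        parts["survival"] = survival_core.loglik(
            data.times, data.events, data.eta(state), state.delta
        )
    else:
        parts["survival"] = 0.0
    if data.n_clusters:
        parts["gp"] = mvn_logpdf_chol(
            state.phi, gp_covariance(data.distances, state.sigma2, state.rho)
        )
    else:
        parts["gp"] = 0.0
    parts["car"] = car_logpdf(state.w, data.region_graph, state.sigmaq2, state.gamma)
    parts["prior"] = log_prior(state, data.priors)
    return parts


def log_posterior(state: ModelState, data: ModelData) -> float:
    """Unnormalised log posterior; −∞ (never an exception) outside support."""
    parts = log_posterior_parts(state, data)
    total = sum(parts.values())
    return float(total) if np.isfinite(total) else -np.inf
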