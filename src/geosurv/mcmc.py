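"""Adaptive Metropolis-within-Gibbs sampling for the geostatistical model.

The posterior is explored in six blocks: the Weibull shape δ (random walk on
log δ), the regression coefficients (β, a) jointly (adaptive multivariate
random walk), the regional effects w and the cluster frailties φ
(single-site random walks against their Gaussian full-conditional priors,
which is fast because a site move shifts η uniformly for all children of that
region or cluster), and the two variance blocks (σ², ρ) and (σq², γ) (joint
random walks, variances and decay on the log scale). Step sizes adapt by a
Robbins–Monro rule towards standard target acceptance rates and freeze after
the adaptation window, so the chain is Markov from there on.

Convergence is diagnosed by the potential scale reduction factor (PSRF)
computed from two or more chains: with W the mean within-chain variance and
B/n the variance of chain means, PSRF = sqrt(((n−1)/n · W + B/n) / W) — the
original between/within comparison without the sampling-variability
degrees-of-freedom correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import gammaln

from .spatial_model import ModelData, ModelState, gp_covariance

ALL_BLOCKS = ("delta", "beta_a", "w", "phi", "sigma2_rho", "sigmaq2_gamma")


@dataclass
class McmcConfig:
    """Sampler protocol: chain length, burn-in, chains, thinning, adaptation."""

    n_iterations: int = 300_000
    burn_in: int = 15_000
    n_chains: int = 2
    thin: int = 30
    seed: int = 0
    adaptation_window: int | None = None  # defaults to burn_in
    target_accept_scalar: float = 0.44
    target_accept_vector: float = 0.234

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.adaptation_window is None:
            self.adaptation_window = self.burn_in


@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned draws per chain, keyed by parameter name."""

    params: dict  # name -> array (n_chains, n_kept)
    acceptance: dict  # block -> mean acceptance rate per chain (list)
    config: McmcConfig
    column_names: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    def pooled(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def names(self) -> list:
        return list(self.params)


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

def gelman_rubin(chains: np.ndarray) -> float:
    """PSRF from an (n_chains, n_draws) array; requires >= 2 chains."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin needs at least two chains")
    n = chains.shape[1]
    if n < 10:
        raise ValueError("gelman_rubin needs at least 10 draws per chain")
    within = float(np.mean(np.var(chains, axis=1, ddof=1)))
    b_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    if within == 0.0:
        return 1.0 if b_over_n == 0.0 else np.inf
    var_hat = (n - 1.0) / n * within + b_over_n
    return float(np.sqrt(var_hat / within))


def summarize(draws: PosteriorDraws, params=None, hrr: bool = False) -> pd.DataFrame:
    """Posterior median and equal-tailed 95% interval per parameter.

    Chains are pooled after burn-in; percentiles use linear interpolation.
    With ``hrr=True`` the exp transform is applied draw-wise first (quantiles
    commute with monotone maps, so this equals exponentiating the summary).
    """
    params = list(params) if params is not None else draws.names()
    rows = []
    for name in params:
        x = draws.pooled(name)
        if hrr:
            x = np.exp(x)
        rows.append(
            {
                "parameter": name,
                "median": float(np.percentile(x, 50)),
                "lower": float(np.percentile(x, 2.5)),
                "upper": float(np.percentile(x, 97.5)),
                "psrf": gelman_rubin(np.exp(draws.params[name]) if hrr else draws.params[name])
                if draws.params[name].shape[0] >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

class _Adapt:
    """Robbins–Monro adaptation of a log step size (scalar or per-site)."""

    def __init__(self, size, init_step, target):
        self.log_step = np.full(size, np.log(init_step)) if size else np.array(np.log(init_step))
        self.target = target
        self.k = 1

    def step(self, i=None):
        ls = self.log_step if i is None else self.log_step[i]
        return np.exp(ls)

    def update(self, accepted, i=None, frozen=False):
        if frozen:
            return
        rate = min(0.1, self.k ** -0.6)
        delta = rate * ((1.0 if accepted else 0.0) - self.target)
        if i is None:
            self.log_step = self.log_step + delta
            self.k += 1
        else:
            self.log_step[i] += delta
            if i == 0:
                self.k += 1


def sample(data: ModelData, config: McmcConfig, update=None, prior_only: bool = False,
           store_phi: bool = True) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler.

    ``update`` restricts sampling to a subset of blocks (others stay at their
    initial values), which is how reduced-model validity checks are run.
    ``prior_only`` drops the survival data term, so the chains target the
    joint prior. Identical seeds give identical draws.
    """
    blocks = tuple(update) if update is not None else ALL_BLOCKS
    unknown = set(blocks) - set(ALL_BLOCKS)
    if unknown:
        raise ValueError(f"unknown blocks: {sorted(unknown)}")
    chain_results = [
        _run_chain(data, config, blocks, prior_only, chain) for chain in range(config.n_chains)
    ]
    params = {
        name: np.stack([res[0][name] for res in chain_results])
        for name in chain_results[0][0]
        if store_phi or not name.startswith("phi[")
    }
    acceptance = {
        block: [res[1][block] for res in chain_results] for block in chain_results[0][1]
    }
    return PosteriorDraws(params=params, acceptance=acceptance, config=config,
                          column_names=list(data.column_names))


def _expon_logpdf(x, rate):
    return np.log(rate) - rate * x


def _ig_logpdf(x, shape, scale):
    return shape * np.log(scale) - gammaln(shape) - (shape + 1.0) * np.log(x) - scale / x


def _gp_loglik(phi, distances, sigma2, rho):
    """N(0, σ²exp(−dρ)) log-density and the precision matrix (for site moves)."""
    m = len(phi)
    if m == 0:
        return 0.0, np.empty((0, 0))
    cov = gp_covariance(distances, sigma2, rho)
    L = np.linalg.cholesky(cov)
    u = sla.solve_triangular(L, phi, lower=True)
    lp = -0.5 * (m * np.log(2.0 * np.pi) + u @ u) - np.sum(np.log(np.diag(L)))
    prec = sla.cho_solve((L, True), np.eye(m))
    return float(lp), prec


def _car_quantities(region_graph, sigmaq2, gamma):
    prec = (np.diag(region_graph.g) - gamma * region_graph.omega) / sigmaq2
    lam = region_graph.car_eigenvalues
    Q = region_graph.n_regions
    logdet_cov = Q * np.log(sigmaq2) - np.sum(np.log(region_graph.g)) \
        - np.sum(np.log1p(-gamma * lam))
    return prec, logdet_cov


def _car_loglik(w, prec, logdet_cov):
    Q = len(w)
    return float(-0.5 * (Q * np.log(2.0 * np.pi) + logdet_cov + w @ prec @ w))


def _jitter_state(state: ModelState, rng, blocks, priors):
    """Overdispersed start for chains beyond the first: N(0, 0.1²) jitter.

    Only parameters of active blocks are perturbed, so reduced-model runs
    keep their conditioning parameters at the documented initial values.
    """
    j = 0.1
    if "delta" in blocks:
        state.delta = float(np.exp(np.log(state.delta) + j * rng.standard_normal()))
    if "beta_a" in blocks:
        state.beta = state.beta + j * rng.standard_normal(state.beta.shape)
        state.a += j * rng.standard_normal()
    if "w" in blocks:
        state.w = state.w + j * rng.standard_normal(state.w.shape)
    if "phi" in blocks:
        state.phi = state.phi + j * rng.standard_normal(state.phi.shape)
    if "sigma2_rho" in blocks:
        state.sigma2 = float(np.exp(np.log(state.sigma2) + j * rng.standard_normal()))
        lo_r, hi_r = priors.rho_support
        width = hi_r - lo_r
        state.rho = float(np.clip(state.rho + 0.05 * width * rng.standard_normal(),
                                  lo_r + 1e-9 * width, hi_r - 1e-9 * width))
    if "sigmaq2_gamma" in blocks:
        state.sigmaq2 = float(np.exp(np.log(state.sigmaq2) + j * rng.standard_normal()))
        lo_g, hi_g = priors.gamma_support
        gwidth = hi_g - lo_g
        state.gamma = float(np.clip(state.gamma + 0.05 * gwidth * rng.standard_normal(),
                                    lo_g + 1e-9 * gwidth, hi_g - 1e-9 * gwidth))


def _run_chain(data: ModelData, config: McmcConfig, blocks, prior_only, chain_index):
    rng = np.random.default_rng([config.seed, chain_index])
    state = data.initial_state()
    if chain_index > 0:
        _jitter_state(state, rng, blocks, data.priors)
    priors = data.priors
    lo_r, hi_r = priors.rho_support
    lo_g, hi_g = priors.gamma_support

    n, m, Q = data.n_children, data.n_clusters, data.n_regions
    use_data = (n > 0) and not prior_only
    t, e = data.times, data.events
    logt = np.log(t) if n else np.empty(0)
    sum_e = float(e.sum()) if n else 0.0
    sum_e_logt = float(e @ logt) if n else 0.0
    X, Z = data.X, data.Z
    cc = data.child_cluster
    cr = data.cluster_region
    region_of_child = cr[cc] if n else np.empty(0, dtype=int)
    E_c = np.bincount(cc, weights=e, minlength=m) if n else np.zeros(m)
    E_q = np.bincount(region_of_child, weights=e, minlength=Q) if n else np.zeros(Q)
    Zq = data.region_Z if data.region_Z is not None else np.zeros(Q)

    p = X.shape[1]
    coef_var = priors.coef_variance

    # caches ---------------------------------------------------------------
    def recompute_eta_u(delta, beta, a, w, phi):
        if n == 0:
            return np.empty(0), np.empty(0)
        eta = X @ beta + (a + w[region_of_child]) * Z + phi[cc]
        u = np.exp(delta * logt + eta)
        return eta, u

    _, phi_prec = _gp_loglik(state.phi, data.distances, state.sigma2, state.rho) \
        if m else (0.0, np.empty((0, 0)))
    v_phi = phi_prec @ state.phi if m else np.empty(0)
    car_prec, car_logdet = _car_quantities(data.region_graph, state.sigmaq2, state.gamma)
    v_w = car_prec @ state.w

    adapt = {
        "delta": _Adapt(0, 0.1, config.target_accept_scalar),
        "beta_a": _Adapt(0, 0.1, config.target_accept_vector),
        "w": _Adapt(Q, 0.2, config.target_accept_scalar),
        "phi": _Adapt(m, 0.3, config.target_accept_scalar),
        "sigma2_rho": _Adapt(0, 0.3, config.target_accept_vector),
        "sigmaq2_gamma": _Adapt(0, 0.3, config.target_accept_vector),
        "recenter_w": _Adapt(0, 0.2, config.target_accept_scalar),
        "recenter_phi": _Adapt(0, 0.2, config.target_accept_scalar),
    }
    # recentering moves: a and the mean of w (and the intercept and the mean
    # of φ) are confounded through η; shifting both in opposite directions
    # leaves the likelihood untouched and is accepted on the priors alone
    recenter_a = ("w" in blocks) and ("beta_a" in blocks)
    has_intercept = bool(data.column_names) and data.column_names[0] == "intercept"
    recenter_phi = ("phi" in blocks) and ("beta_a" in blocks) and has_intercept and m > 0
    acc = {b: 0 for b in blocks}
    att = {b: 0 for b in blocks}

    # adaptive covariance for the (beta, a) block, seeded from the non-spatial
    # MLE's inverse information so the intercept/a·Z correlation is in the
    # proposal from the start
    coef_mean = np.zeros(p + 1)
    coef_m2 = np.zeros((p + 1, p + 1))
    coef_count = 0
    coef_chol = np.eye(p + 1)
    if use_data and "beta_a" in blocks:
        try:
            from .screening import fit_weibull_ph

            mle = fit_weibull_ph(t, e, np.column_stack([X, Z]))
            if mle.vcov is not None and np.all(np.isfinite(mle.vcov)):
                coef_chol = np.linalg.cholesky(
                    mle.vcov[1:, 1:] + 1e-10 * np.eye(p + 1)
                )
        except (ValueError, np.linalg.LinAlgError):
            pass

    n_kept = (config.n_iterations - config.burn_in) // config.thin
    store = {
        "delta": np.empty(n_kept), "a": np.empty(n_kept),
        "sigma2": np.empty(n_kept), "rho": np.empty(n_kept),
        "sigmaq2": np.empty(n_kept), "gamma": np.empty(n_kept),
    }
    beta_store = np.empty((n_kept, p))
    w_store = np.empty((n_kept, Q))
    phi_store = np.empty((n_kept, m))
    kept = 0

    log_u = np.log(rng.uniform(size=(config.n_iterations, 6)) + 1e-300)

    for it in range(config.n_iterations):
        frozen = it >= config.adaptation_window
        eta, u = recompute_eta_u(state.delta, state.beta, state.a, state.w, state.phi)
        if n:
            S_c = np.bincount(cc, weights=u, minlength=m)
            S_q = np.bincount(region_of_child, weights=u, minlength=Q)
            total_u = float(u.sum())
        else:
            S_c, S_q, total_u = np.zeros(m), np.zeros(Q), 0.0

        # -- delta ---------------------------------------------------------
        if "delta" in blocks:
            att["delta"] += 1
            step = float(adapt["delta"].step())
            logd_new = np.log(state.delta) + step * rng.standard_normal()
            d_new = float(np.exp(logd_new))
            if use_data:
                u_new = np.exp(d_new * logt + eta)
                dll = (sum_e * (logd_new - np.log(state.delta))
                       + (d_new - state.delta) * sum_e_logt
                       - (float(u_new.sum()) - total_u))
            else:
                u_new, dll = u, 0.0
            dlp = (_expon_logpdf(d_new, priors.delta_rate)
                   - _expon_logpdf(state.delta, priors.delta_rate)
                   + (logd_new - np.log(state.delta)))  # log-scale Jacobian
            ok = (dll + dlp) > log_u[it, 0]
            if ok:
                state.delta = d_new
                if use_data:
                    u = u_new
                    S_c = np.bincount(cc, weights=u, minlength=m)
                    S_q = np.bincount(region_of_child, weights=u, minlength=Q)
                    total_u = float(u.sum())
                acc["delta"] += 1
            adapt["delta"].update(ok, frozen=frozen)

        # -- (beta, a) -----------------------------------------------------
        if "beta_a" in blocks:
            att["beta_a"] += 1
            step = float(adapt["beta_a"].step())
            prop = step * (coef_chol @ rng.standard_normal(p + 1))
            d_beta, d_a = prop[:p], prop[p]
            if use_data:
                d_eta = X @ d_beta + d_a * Z
                u_new = u * np.exp(d_eta)
                dll = float(e @ d_eta) - (float(u_new.sum()) - total_u)
            else:
                u_new, dll = u, 0.0
            beta_new = state.beta + d_beta
            a_new = state.a + d_a
            dlp = (-0.5 * (float(beta_new @ beta_new) + a_new ** 2
                           - float(state.beta @ state.beta) - state.a ** 2) / coef_var)
            ok = (dll + dlp) > log_u[it, 1]
            if ok:
                state.beta, state.a = beta_new, a_new
                if use_data:
                    eta = eta + d_eta
                    u = u_new
                    S_c = np.bincount(cc, weights=u, minlength=m)
                    S_q = np.bincount(region_of_child, weights=u, minlength=Q)
                    total_u = float(u.sum())
                acc["beta_a"] += 1
            adapt["beta_a"].update(ok, frozen=frozen)
            if not frozen:
                coef = np.concatenate([state.beta, [state.a]])
                coef_count += 1
                delta_mean = coef - coef_mean
                coef_mean = coef_mean + delta_mean / coef_count
                coef_m2 = coef_m2 + np.outer(delta_mean, coef - coef_mean)
                if coef_count > 1000 and coef_count % 100 == 0:
                    cov = coef_m2 / (coef_count - 1) + 1e-8 * np.eye(p + 1)
                    try:
                        coef_chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass

        # -- w (single-site) -------------------------------------------------
        if "w" in blocks:
            z_norm = rng.standard_normal(Q)
            logu_w = np.log(rng.uniform(size=Q) + 1e-300)
            n_acc_w = 0
            for q in range(Q):
                eps = float(adapt["w"].step(q)) * z_norm[q]
                d_prior = -(0.5 * car_prec[q, q] * eps * eps + eps * v_w[q])
                if use_data:
                    factor = np.exp(eps * Zq[q])
                    dll = eps * Zq[q] * E_q[q] - (factor - 1.0) * S_q[q]
                else:
                    dll = 0.0
                ok = (dll + d_prior) > logu_w[q]
                if ok:
                    state.w[q] += eps
                    v_w = v_w + eps * car_prec[:, q]
                    if use_data:
                        dS = (factor - 1.0) * S_q[q]
                        S_q[q] *= factor
                        S_c[cr == q] *= factor
                        total_u += dS
                    n_acc_w += 1
                adapt["w"].update(ok, i=q, frozen=frozen)
            att["w"] += Q
            acc["w"] += n_acc_w
            if recenter_a:
                s = float(adapt["recenter_w"].step()) * rng.standard_normal()
                one_Pw = car_prec.sum(axis=0)
                d_prior = (-0.5 * (s * s * one_Pw.sum()) + s * float(v_w.sum())
                           - 0.5 * ((state.a + s) ** 2 - state.a ** 2) / coef_var)
                ok = d_prior > np.log(rng.uniform() + 1e-300)
                if ok:
                    state.a += s
                    state.w = state.w - s
                    v_w = v_w - s * one_Pw
                adapt["recenter_w"].update(ok, frozen=frozen)

        # -- phi (single-site) ----------------------------------------------
        if "phi" in blocks and m:
            z_norm = rng.standard_normal(m)
            logu_p = np.log(rng.uniform(size=m) + 1e-300)
            n_acc_phi = 0
            for i in range(m):
                eps = float(adapt["phi"].step(i)) * z_norm[i]
                d_prior = -(0.5 * phi_prec[i, i] * eps * eps + eps * v_phi[i])
                if use_data:
                    factor = np.exp(eps)
                    dll = eps * E_c[i] - (factor - 1.0) * S_c[i]
                else:
                    dll = 0.0
                ok = (dll + d_prior) > logu_p[i]
                if ok:
                    state.phi[i] += eps
                    v_phi = v_phi + eps * phi_prec[:, i]
                    if use_data:
                        dS = (factor - 1.0) * S_c[i]
                        S_c[i] *= factor
                        S_q[cr[i]] += dS
                        total_u += dS
                    n_acc_phi += 1
                adapt["phi"].update(ok, i=i, frozen=frozen)
            att["phi"] += m
            acc["phi"] += n_acc_phi
            if recenter_phi:
                s = float(adapt["recenter_phi"].step()) * rng.standard_normal()
                one_L = phi_prec.sum(axis=0)
                b0 = state.beta[0]
                d_prior = (-0.5 * (s * s * one_L.sum()) + s * float(v_phi.sum())
                           - 0.5 * ((b0 + s) ** 2 - b0 ** 2) / coef_var)
                ok = d_prior > np.log(rng.uniform() + 1e-300)
                if ok:
                    state.beta[0] += s
                    state.phi = state.phi - s
                    v_phi = v_phi - s * one_L
                adapt["recenter_phi"].update(ok, frozen=frozen)

        # -- (sigma2, rho) ---------------------------------------------------
        if "sigma2_rho" in blocks:
            att["sigma2_rho"] += 1
            step = float(adapt["sigma2_rho"].step())
            prop = step * rng.standard_normal(2)
            s2_new = float(np.exp(np.log(state.sigma2) + prop[0]))
            rho_new = float(np.exp(np.log(state.rho) + prop[1]))
            ok = False
            if lo_r <= rho_new <= hi_r:
                if m:
                    gp_old, _ = _gp_recompute_lp(state.phi, phi_prec)
                    try:
                        gp_new, prec_new = _gp_loglik(state.phi, data.distances, s2_new, rho_new)
                    except np.linalg.LinAlgError:
                        gp_new, prec_new = -np.inf, None
                else:
                    gp_old, gp_new, prec_new = 0.0, 0.0, phi_prec
                dlp = (_ig_logpdf(s2_new, priors.ig_shape, priors.ig_scale)
                       - _ig_logpdf(state.sigma2, priors.ig_shape, priors.ig_scale)
                       + np.log(s2_new) - np.log(state.sigma2)
                       + np.log(rho_new) - np.log(state.rho))  # Jacobians
                ok = np.isfinite(gp_new) and (gp_new - gp_old + dlp) > log_u[it, 4]
                if ok:
                    state.sigma2, state.rho = s2_new, rho_new
                    phi_prec = prec_new
                    v_phi = phi_prec @ state.phi if m else v_phi
                    acc["sigma2_rho"] += 1
            adapt["sigma2_rho"].update(ok, frozen=frozen)

        # -- (sigmaq2, gamma) -------------------------------------------------
        if "sigmaq2_gamma" in blocks:
            att["sigmaq2_gamma"] += 1
            step = float(adapt["sigmaq2_gamma"].step())
            prop = step * rng.standard_normal(2)
            sq_new = float(np.exp(np.log(state.sigmaq2) + prop[0]))
            gamma_new = state.gamma + 0.3 * step * prop[1]
            ok = False
            if lo_g < gamma_new < hi_g:
                prec_new, logdet_new = _car_quantities(data.region_graph, sq_new, gamma_new)
                car_old = _car_loglik(state.w, car_prec, car_logdet)
                car_new = _car_loglik(state.w, prec_new, logdet_new)
                dlp = (_ig_logpdf(sq_new, priors.ig_shape, priors.ig_scale)
                       - _ig_logpdf(state.sigmaq2, priors.ig_shape, priors.ig_scale)
                       + np.log(sq_new) - np.log(state.sigmaq2))
                ok = (car_new - car_old + dlp) > log_u[it, 5]
                if ok:
                    state.sigmaq2, state.gamma = sq_new, gamma_new
                    car_prec, car_logdet = prec_new, logdet_new
                    v_w = car_prec @ state.w
                    acc["sigmaq2_gamma"] += 1
            adapt["sigmaq2_gamma"].update(ok, frozen=frozen)

        # -- record -----------------------------------------------------------
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and kept < n_kept:
            store["delta"][kept] = state.delta
            store["a"][kept] = state.a
            store["sigma2"][kept] = state.sigma2
            store["rho"][kept] = state.rho
            store["sigmaq2"][kept] = state.sigmaq2
            store["gamma"][kept] = state.gamma
            beta_store[kept] = state.beta
            w_store[kept] = state.w
            phi_store[kept] = state.phi
            kept += 1

    out = dict(store)
    for j, name in enumerate(data.column_names):
        out[f"beta[{name}]"] = beta_store[:, j]
    for j, rid in enumerate(data.region_graph.region_ids):
        out[f"w[{rid}]"] = w_store[:, j]
    for j in range(m):
        out[f"phi[{j}]"] = phi_store[:, j]
    rates = {b: (acc.get(b, 0) / att[b] if att.get(b) else np.nan) for b in blocks}
    return out, rates


def _gp_recompute_lp(phi, prec):
    """GP log-density of φ from its (already jittered) precision matrix."""
    m = len(phi)
    if m == 0:
        return 0.0, prec
    sign, logdet_prec = np.linalg.slogdet(prec)
    lp = -0.5 * (m * np.log(2.0 * np.pi) - logdet_prec + phi @ prec @ phi)
    return float(lp), prec
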