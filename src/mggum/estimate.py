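"""Bayesian estimation of the MGGUM with covariates.

The posterior combines the unfolding-model likelihood with the priors that
are standard for direction-informed GGUM estimation:

* ``alpha_i ~ logN(0, 0.5)`` (second argument an SD, sampler convention),
* ``delta_i ~ N(-1, 1)`` truncated to ``delta <= 0`` for negative items,
  ``N(1, 1)`` truncated to ``delta >= 0`` for positive items, ``N(0, 1)``
  unbounded for neutral items,
* ``tau ~ N(-2, 2)`` with two response options; ``N(-3, 2), N(-2, 2),
  N(-1, 2)`` with four,
* ``theta_j ~ MVN(X_j beta, omega)`` with ``omega`` restricted to a
  correlation matrix (LKJ(1) prior) and the residual scale fixed at one per
  dimension for identification; ``theta_j ~ MVN(0, omega)`` without
  covariates,
* ``beta_pd ~ N(0, 1)`` independently.

Sampling is Hamiltonian Monte Carlo over every continuous parameter with
analytic gradients, on unconstrained scales: ``log alpha``, ``log |delta|``
for bounded locations, raw thresholds and coefficients, the trait
correlation matrix through tanh-transformed canonical partial correlations
of its Cholesky factor, and NON-CENTERED traits ``theta = X beta + eta L'``
with ``eta ~ N(0, I)``.  Involutive Metropolis proposals (item location
sign flips, per-person trait sign flips, warmup-time whole-dimension
reflections) mix the discrete sub-modes of the unfolding likelihood that
gradient dynamics cross only rarely, and the likelihood is annealed over
early warmup so chains settle into the dominant basin.  Step size is tuned
by dual averaging toward 0.9 acceptance and a block-diagonal metric (dense
per-item blocks, diagonal elsewhere) is estimated during warmup.
Convergence is gated on the Gelman-Rubin potential scale reduction factor
computed for every retained scalar parameter.

The likelihood/gradient inner loop exists twice: a numba-compiled kernel used
by the sampler and the vectorized numpy reference in :mod:`mggum.kernels`;
their agreement is pinned by the test-suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import solve_triangular

from .kernels import ItemBank, ResponseMatrix, ResponseScale

__all__ = [
    "classify_item_direction",
    "PriorSpec",
    "McmcConfig",
    "MggumModel",
    "PosteriorFit",
    "build_model",
    "fit",
    "gelman_rubin",
    "covariate_significance",
    "read_responses",
    "read_itemmap",
    "read_covariates",
    "load_fit",
]


def classify_item_direction(delta: float) -> str:
    """Direction label from a location parameter.

    delta < -1.5 -> negative; delta > 1.5 -> positive; otherwise (boundaries
    included) neutral.
    """
    if delta < -1.5:
        return "negative"
    if delta > 1.5:
        return "positive"
    return "neutral"


# ---------------------------------------------------------------------------
# priors and configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters; all second arguments are standard deviations."""

    delta_neutral: Tuple[float, float] = (0.0, 1.0)
    delta_negative: Tuple[float, float] = (-1.0, 1.0)   # with bound delta <= 0
    delta_positive: Tuple[float, float] = (1.0, 1.0)    # with bound delta >= 0
    tau: Tuple[Tuple[float, float], ...] = ((-2.0, 2.0),)
    alpha_lognormal: Tuple[float, float] = (0.0, 0.5)
    beta_sd: float = 1.0
    lkj_shape: float = 1.0

    def __post_init__(self) -> None:
        sds = [self.delta_neutral[1], self.delta_negative[1], self.delta_positive[1],
               self.alpha_lognormal[1], self.beta_sd] + [t[1] for t in self.tau]
        if min(sds) <= 0:
            raise ValueError("all prior standard deviations must be positive")

    @classmethod
    def for_scale(cls, scale: ResponseScale) -> "PriorSpec":
        if scale.C == 1:
            tau = ((-2.0, 2.0),)
        elif scale.C == 3:
            tau = ((-3.0, 2.0), (-2.0, 2.0), (-1.0, 2.0))
        else:  # generic fallback: centre every threshold at -2
            tau = tuple((-2.0, 2.0) for _ in range(scale.C))
        return cls(tau=tau)


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings: 2 chains of 2000 iterations, first 1000 warmup."""

    n_chains: int = 2
    n_iterations: int = 2000
    n_burnin: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.05
    target_accept: float = 0.9
    max_leapfrog: int = 32
    pointwise_loglik: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 for the Gelman-Rubin diagnostic")
        if not (0 < self.n_burnin < self.n_iterations):
            raise ValueError("need 0 < n_burnin < n_iterations")

    @property
    def n_keep(self) -> int:
        return self.n_iterations - self.n_burnin


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

_DIR_CODE = {"neutral": 0, "positive": 1, "negative": -1}


@dataclass
class MggumModel:
    """Data, structure and priors bound together, ready to sample."""

    responses: ResponseMatrix
    scale: ResponseScale
    trait: np.ndarray            # (I,) 0-based loading dimension
    dir_code: np.ndarray         # (I,) 0 neutral, +1 positive, -1 negative
    X: Optional[np.ndarray]
    priors: PriorSpec

    @property
    def n_persons(self) -> int:
        return self.responses.n_persons

    @property
    def n_items(self) -> int:
        return self.responses.n_items

    @property
    def n_traits(self) -> int:
        return int(self.trait.max()) + 1

    @property
    def n_covariates(self) -> int:
        return 0 if self.X is None else self.X.shape[1]

    def anchored_dims(self) -> np.ndarray:
        """Boolean (D,): True where some item on the dimension has a bounded
        (non-neutral) location prior, which pins the reflection sign."""
        out = np.zeros(self.n_traits, dtype=bool)
        for d in range(self.n_traits):
            out[d] = np.any(self.dir_code[self.trait == d] != 0)
        return out


def build_model(responses: ResponseMatrix, items: ItemBank, scale: ResponseScale,
                X: Optional[np.ndarray] = None,
                priors: Optional[PriorSpec] = None) -> MggumModel:
    """Assemble the posterior for sampling.

    Only the item->trait map and the direction labels are taken from
    ``items``; any generating parameter values it carries are ignored.
    Covariates must be complete (missingness is supported in responses only).
    """
    responses.validate_scale(scale)
    if items.n_items != responses.n_items:
        raise ValueError("item bank and responses disagree on the number of items")
    all_missing = responses.missing_mask.all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"items with no observed responses: columns {np.where(all_missing)[0]}"
        )
    if X is not None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != responses.n_persons:
            raise ValueError("covariate rows must match the number of persons")
        if np.isnan(X).any():
            raise ValueError(
                "missing covariate values are unsupported; only response "
                "missingness is handled"
            )
        if X.shape[1] == 0:
            X = None
    if priors is None:
        priors = PriorSpec.for_scale(scale)
    if len(priors.tau) != scale.C:
        raise ValueError("priors.tau must have one (mean, sd) pair per threshold")
    dir_code = np.array([_DIR_CODE[str(d)] for d in items.direction], dtype=np.int64)
    return MggumModel(responses=responses, scale=scale,
                      trait=items.dimension.astype(np.int64).copy(),
                      dir_code=dir_code, X=X, priors=priors)


# ---------------------------------------------------------------------------
# likelihood + gradient kernel (numba)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _ll_grad_kernel(z, obs, trait, alpha, delta, tau_cs, theta, C, M,
                    g_alpha, g_delta, g_tau, g_theta):
    """Total log-likelihood and in-place gradients w.r.t. the constrained
    item parameters and theta.  ``tau_cs`` is the (I, C+1) threshold cumsum
    with a leading zero; ``obs`` marks non-missing cells."""
    J, I = z.shape
    ll = 0.0
    p1 = np.empty(C + 1)
    p2 = np.empty(C + 1)
    for j in range(J):
        for i in range(I):
            if not obs[j, i]:
                continue
            a = alpha[i]
            x = theta[j, trait[i]] - delta[i]
            mx = -1.0e308
            for w in range(C + 1):
                s = tau_cs[i, w]
                t1 = a * (w * x - s)
                t2 = a * ((M - w) * x - s)
                p1[w] = t1
                p2[w] = t2
                if t1 > mx:
                    mx = t1
                if t2 > mx:
                    mx = t2
            denom = 0.0
            rbar = 0.0
            sbar = 0.0
            for w in range(C + 1):
                e1 = np.exp(p1[w] - mx)
                e2 = np.exp(p2[w] - mx)
                p1[w] = e1
                p2[w] = e2
                denom += e1 + e2
                rbar += w * e1 + (M - w) * e2
                sbar += (e1 + e2) * tau_cs[i, w]
            zi = z[j, i]
            e1o = p1[zi]
            e2o = p2[zi]
            num = e1o + e2o
            if num <= 0.0:
                # observed category underflowed: reject this point outright
                return -np.inf
            ll += np.log(num) - np.log(denom)
            r_obs = (zi * e1o + (M - zi) * e2o) / num
            dx = a * (r_obs - rbar / denom)
            g_theta[j, trait[i]] += dx
            g_delta[i] -= dx
            g_alpha[i] += x * (r_obs - rbar / denom) - (tau_cs[i, zi] - sbar / denom)
            # suffix sums over categories w >= m give the tau_m gradient
            suffix = 0.0
            for m in range(C, 0, -1):
                suffix += p1[m] + p2[m]
                ind = 1.0 if zi >= m else 0.0
                g_tau[i, m - 1] += -a * (ind - suffix / denom)
    return ll


@njit(cache=True, fastmath=False)
def _item_ll_kernel(z, obs, trait, alpha, delta, tau_cs, theta, C, M, out):
    """Per-item total log-likelihood (the likelihood factorizes over items
    given theta, so itemwise Metropolis moves only need these sums)."""
    J, I = z.shape
    out[:] = 0.0
    for j in range(J):
        for i in range(I):
            if not obs[j, i]:
                continue
            a = alpha[i]
            x = theta[j, trait[i]] - delta[i]
            mx = -1.0e308
            for w in range(C + 1):
                s = tau_cs[i, w]
                t1 = a * (w * x - s)
                t2 = a * ((M - w) * x - s)
                if t1 > mx:
                    mx = t1
                if t2 > mx:
                    mx = t2
            denom = 0.0
            num = 0.0
            for w in range(C + 1):
                s = tau_cs[i, w]
                e = np.exp(a * (w * x - s) - mx) + np.exp(a * ((M - w) * x - s) - mx)
                denom += e
                if w == z[j, i]:
                    num = e
            if num <= 0.0:
                out[i] = -np.inf
            else:
                out[i] += np.log(num) - np.log(denom)


@njit(cache=True, fastmath=False)
def _person_ll_kernel(z, obs, trait, alpha, delta, tau_cs, theta, C, M, out):
    """Per-person total log-likelihood (persons are independent given the
    item parameters, so personwise Metropolis moves only need these sums)."""
    J, I = z.shape
    out[:] = 0.0
    for j in range(J):
        acc = 0.0
        for i in range(I):
            if not obs[j, i]:
                continue
            a = alpha[i]
            x = theta[j, trait[i]] - delta[i]
            mx = -1.0e308
            for w in range(C + 1):
                s = tau_cs[i, w]
                t1 = a * (w * x - s)
                t2 = a * ((M - w) * x - s)
                if t1 > mx:
                    mx = t1
                if t2 > mx:
                    mx = t2
            denom = 0.0
            num = 0.0
            for w in range(C + 1):
                s = tau_cs[i, w]
                e = np.exp(a * (w * x - s) - mx) + np.exp(a * ((M - w) * x - s) - mx)
                denom += e
                if w == z[j, i]:
                    num = e
            if num <= 0.0:
                acc = -np.inf
                break
            acc += np.log(num) - np.log(denom)
        out[j] = acc


@njit(cache=True, fastmath=False)
def _pointwise_ll_kernel(z, obs, trait, alpha, delta, tau_cs, theta, C, M, out):
    """Per-observation log-likelihood, row-major over observed cells."""
    J, I = z.shape
    k = 0
    for j in range(J):
        for i in range(I):
            if not obs[j, i]:
                continue
            a = alpha[i]
            x = theta[j, trait[i]] - delta[i]
            mx = -1.0e308
            for w in range(C + 1):
                s = tau_cs[i, w]
                t1 = a * (w * x - s)
                t2 = a * ((M - w) * x - s)
                if t1 > mx:
                    mx = t1
                if t2 > mx:
                    mx = t2
            denom = 0.0
            num = 0.0
            for w in range(C + 1):
                s = tau_cs[i, w]
                e = np.exp(a * (w * x - s) - mx) + np.exp(a * ((M - w) * x - s) - mx)
                denom += e
                if w == z[j, i]:
                    num = e
            out[k] = np.log(num) - np.log(denom)
            k += 1
    return k


# ---------------------------------------------------------------------------
# posterior (unconstrained parametrization) for the HMC block
# ---------------------------------------------------------------------------


@njit(cache=True)
def _cpc_to_cholesky(z: np.ndarray, D: int) -> np.ndarray:
    """Lower Cholesky factor of a correlation matrix from canonical partial
    correlations z[i, j] (j < i); rows have unit norm by construction."""
    L = np.zeros((D, D))
    L[0, 0] = 1.0
    for i in range(1, D):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[i, j] * np.sqrt(rem)
            rem *= 1.0 - z[i, j] ** 2
        L[i, i] = np.sqrt(rem)
    return L


@njit(cache=True)
def _cpc_backprop(zm: np.ndarray, L: np.ndarray, G_L: np.ndarray,
                  D: int) -> np.ndarray:
    """Chain rule of a Cholesky-space gradient back to the CPCs z."""
    g_z = np.zeros((D, D))
    for i in range(1, D):
        prods = np.empty(i + 1)
        rem = 1.0
        for j in range(i):
            prods[j] = np.sqrt(rem)
            rem *= 1.0 - zm[i, j] ** 2
        prods[i] = np.sqrt(rem)
        for m in range(i):
            g = G_L[i, m] * prods[m]
            fac = -zm[i, m] / (1.0 - zm[i, m] ** 2)
            for j in range(m + 1, i):
                g += G_L[i, j] * L[i, j] * fac
            g += G_L[i, i] * L[i, i] * fac
            g_z[i, m] = g
    return g_z


@njit(cache=True)
def _full_logp_grad(q, z, obs, trait, C, M, bounded, sign,
                    delta_mean, delta_sd, tau_mean, tau_sd, ua_mean, ua_sd,
                    X, beta_sd, cpc_i, cpc_j, cpc_exp, J, I, D, K, P,
                    lik_weight):
    """Whole log-posterior and gradient in one compiled pass.

    Mirrors the parametrization documented on _Posterior; returns
    (lp, grad) with lp = -inf (and an unusable grad) on numerical
    rejection (likelihood underflow or a degenerate correlation factor).
    """
    n_q = 2 * I + I * C + J * D + K + P * D
    grad = np.zeros(n_q)
    o_vd = I
    o_tau = 2 * I
    o_eta = o_tau + I * C
    o_y = o_eta + J * D
    o_beta = o_y + K

    ua = q[0:I]
    vd = q[o_vd:o_tau]
    alpha = np.empty(I)
    delta = np.empty(I)
    for i in range(I):
        a = ua[i] if ua[i] < 50.0 else 50.0
        alpha[i] = np.exp(a)
        if bounded[i]:
            v = vd[i] if vd[i] < 50.0 else 50.0
            delta[i] = sign[i] * np.exp(v)
        else:
            delta[i] = vd[i]
    tau_cs = np.zeros((I, C + 1))
    for i in range(I):
        s = 0.0
        for k in range(C):
            s += q[o_tau + i * C + k]
            tau_cs[i, k + 1] = s

    # correlation Cholesky factor from the CPCs
    zm = np.zeros((D, D))
    zt = np.empty(K)
    for k in range(K):
        zt[k] = np.tanh(q[o_y + k])
        if abs(zt[k]) >= 1.0 - 1e-15:
            return -np.inf, grad
        zm[cpc_i[k], cpc_j[k]] = zt[k]
    L = _cpc_to_cholesky(zm, D)
    for d in range(D):
        if L[d, d] < 1e-12:
            return -np.inf, grad

    # theta = X beta + eta L' (L lower triangular)
    eta = q[o_eta:o_y].reshape(J, D)
    theta = np.empty((J, D))
    for j in range(J):
        for d in range(D):
            s = 0.0
            for c in range(d + 1):
                s += eta[j, c] * L[d, c]
            for p in range(P):
                s += X[j, p] * q[o_beta + p * D + d]
            theta[j, d] = s

    g_alpha = grad[0:I]
    g_delta = grad[o_vd:o_tau]
    g_tau = grad[o_tau:o_eta].reshape(I, C)
    g_theta = np.zeros((J, D))
    ll = _ll_grad_kernel(z, obs, trait, alpha, delta, tau_cs, theta,
                         C, M, g_alpha, g_delta, g_tau, g_theta)
    if not np.isfinite(ll):
        return -np.inf, grad
    if lik_weight != 1.0:
        ll *= lik_weight
        for i in range(2 * I + I * C):
            grad[i] *= lik_weight
        for j in range(J):
            for d in range(D):
                g_theta[j, d] *= lik_weight
    lp = ll

    # eta prior (iid standard normal) and chain rule through L
    for j in range(J):
        for c in range(D):
            s = 0.0
            for d in range(c, D):
                s += g_theta[j, d] * L[d, c]
            grad[o_eta + j * D + c] = s - eta[j, c]
            lp -= 0.5 * eta[j, c] ** 2
    if K:
        G_L = np.zeros((D, D))
        for d in range(D):
            for c in range(d + 1):
                s = 0.0
                for j in range(J):
                    s += g_theta[j, d] * eta[j, c]
                G_L[d, c] = s
        g_z = _cpc_backprop(zm, L, G_L, D)
        for k in range(K):
            lp += (cpc_exp[k] + 1.0) * np.log1p(-zt[k] ** 2)
            grad[o_y + k] = (g_z[cpc_i[k], cpc_j[k]] * (1.0 - zt[k] ** 2)
                             - (cpc_exp[k] + 1.0) * 2.0 * zt[k])
    # regression coefficients
    for p in range(P):
        for d in range(D):
            b = q[o_beta + p * D + d]
            s = 0.0
            for j in range(J):
                s += X[j, p] * g_theta[j, d]
            grad[o_beta + p * D + d] = s - b / beta_sd ** 2
            lp -= 0.5 * (b / beta_sd) ** 2
    # item-parameter priors (alpha on the log scale, bounded-delta Jacobian)
    for i in range(I):
        lp -= 0.5 * ((ua[i] - ua_mean) / ua_sd) ** 2
        g_alpha[i] = alpha[i] * g_alpha[i] - (ua[i] - ua_mean) / ua_sd ** 2
        dp = -(delta[i] - delta_mean[i]) / delta_sd[i] ** 2
        lp -= 0.5 * ((delta[i] - delta_mean[i]) / delta_sd[i]) ** 2
        if bounded[i]:
            lp += vd[i]
            v = vd[i] if vd[i] < 50.0 else 50.0
            g_delta[i] = (g_delta[i] + dp) * (sign[i] * np.exp(v)) + 1.0
        else:
            g_delta[i] = g_delta[i] + dp
        for k in range(C):
            t = q[o_tau + i * C + k]
            lp -= 0.5 * ((t - tau_mean[k]) / tau_sd[k]) ** 2
            g_tau[i, k] -= (t - tau_mean[k]) / tau_sd[k] ** 2
    return lp, grad


class _Posterior:
    """Log-density and gradient of the full unconstrained posterior state.

    Unconstrained vector layout: [u_alpha (I), v_delta (I), tau (I*C),
    eta (J*D), y (D(D-1)/2), beta (P*D)] with alpha = exp(u), delta =
    sign * exp(v) for bounded items (log-Jacobians included), omega
    parametrized by canonical partial correlations z = tanh(y) through its
    Cholesky factor L, and the latent traits NON-CENTERED:

        theta = X beta + eta L',   eta_jd ~ N(0, 1) iid.

    The non-centered form removes the funnel between the traits and their
    correlation matrix that makes weakly informed fits mix slowly.  Under
    the LKJ(1) prior the CPCs are independent with density
    (1 - z^2)^((D - 2 - c)/2) where c is the size of the conditioning set,
    which combines with the tanh Jacobian to (c_exp + 1) * log(1 - z^2).
    """

    def __init__(self, model: MggumModel):
        self.model = model
        self.I = model.n_items
        self.J = model.n_persons
        self.D = model.n_traits
        self.C = model.scale.C
        self.M = model.scale.M
        self.z = np.ascontiguousarray(model.responses.values, dtype=np.int64)
        self.obs = np.ascontiguousarray(~model.responses.missing_mask)
        self.trait = np.ascontiguousarray(model.trait, dtype=np.int64)
        pr = model.priors
        self.tau_mean = np.array([t[0] for t in pr.tau])
        self.tau_sd = np.array([t[1] for t in pr.tau])
        code = model.dir_code
        self.bounded = code != 0
        self.sign = np.where(code < 0, -1.0, 1.0)
        self.delta_mean = np.where(code == 0, pr.delta_neutral[0],
                                   np.where(code > 0, pr.delta_positive[0],
                                            pr.delta_negative[0]))
        self.delta_sd = np.where(code == 0, pr.delta_neutral[1],
                                 np.where(code > 0, pr.delta_positive[1],
                                          pr.delta_negative[1]))
        self.ua_sd = pr.alpha_lognormal[1]
        self.ua_mean = pr.alpha_lognormal[0]
        self.K = self.D * (self.D - 1) // 2     # free correlation parameters
        self.P = model.n_covariates
        self.X = model.X
        self._X_arr = (np.ascontiguousarray(model.X, dtype=np.float64)
                       if self.P else np.zeros((self.J, 0)))
        self.beta_sd = pr.beta_sd
        base = 2 * self.I + self.I * self.C
        ny = base + self.J * self.D
        self.n_q = ny + self.K + self.P * self.D
        self._s = (slice(0, self.I), slice(self.I, 2 * self.I),
                   slice(2 * self.I, base),
                   slice(base, ny),
                   slice(ny, ny + self.K),
                   slice(ny + self.K, self.n_q))
        # CPC index bookkeeping: pair (i, j), j < i, conditioning-set size j
        self.cpc_pairs = [(i, j) for i in range(1, self.D) for j in range(i)]
        self.cpc_i = np.array([i for i, j in self.cpc_pairs], dtype=int)
        self.cpc_j = np.array([j for i, j in self.cpc_pairs], dtype=int)
        self.cpc_exp = np.array([(self.D - 2.0 - j) / 2.0
                                 for i, j in self.cpc_pairs])
        self._tril_mask = np.tril(np.ones((self.D, self.D)))
        # likelihood tempering weight; ramped 0 -> 1 during early warmup so
        # chains anneal into the dominant basin instead of freezing into a
        # self-consistent but inferior (theta, item) configuration
        self.lik_weight = 1.0

    def beta_of(self, q: np.ndarray) -> Optional[np.ndarray]:
        if not self.P:
            return None
        return q[self._s[5]].reshape(self.P, self.D)

    def mean_of(self, q: np.ndarray) -> np.ndarray:
        if not self.P:
            return np.zeros((self.J, self.D))
        return self.X @ self.beta_of(q)

    def unpack(self, q: np.ndarray):
        """Constrained values at q; theta is reconstructed from the
        non-centered (eta, y, beta) blocks."""
        ua = q[self._s[0]]
        vd = q[self._s[1]]
        tau = q[self._s[2]].reshape(self.I, self.C)
        eta = q[self._s[3]].reshape(self.J, self.D)
        L = self.chol_omega(q)
        theta = eta @ L.T
        if self.P:
            theta = theta + self.mean_of(q)
        alpha = np.exp(np.minimum(ua, 50.0))
        evd = np.exp(np.minimum(vd, 50.0))
        delta = np.where(self.bounded, self.sign * evd, vd)
        return ua, vd, tau, theta, alpha, delta

    def _z_matrix(self, y: np.ndarray) -> np.ndarray:
        z = np.zeros((self.D, self.D))
        z[self.cpc_i, self.cpc_j] = np.tanh(y)
        return z

    def chol_omega(self, q: np.ndarray) -> np.ndarray:
        """Lower Cholesky factor of the trait correlation matrix at q."""
        if self.K == 0:
            return np.eye(self.D)
        return _cpc_to_cholesky(self._z_matrix(q[self._s[4]]), self.D)

    def omega(self, q: np.ndarray) -> np.ndarray:
        L = self.chol_omega(q)
        return L @ L.T

    def logp_grad(self, q: np.ndarray) -> Tuple[float, np.ndarray]:
        """Log-posterior and gradient at q (single compiled pass)."""
        lp, grad = _full_logp_grad(
            q, self.z, self.obs, self.trait, self.C, self.M,
            self.bounded, self.sign, self.delta_mean, self.delta_sd,
            self.tau_mean, self.tau_sd, self.ua_mean, self.ua_sd,
            self._X_arr, self.beta_sd, self.cpc_i, self.cpc_j, self.cpc_exp,
            self.J, self.I, self.D, self.K, self.P, self.lik_weight)
        if not np.isfinite(lp):
            return -np.inf, np.zeros(self.n_q)
        return lp, grad

    def item_loglik(self, alpha: np.ndarray, delta: np.ndarray,
                    tau: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Total log-likelihood per item at the given constrained values."""
        tau_cs = np.zeros((self.I, self.C + 1))
        tau_cs[:, 1:] = np.cumsum(tau, axis=1)
        out = np.empty(self.I)
        _item_ll_kernel(self.z, self.obs, self.trait, alpha, delta,
                        np.ascontiguousarray(tau_cs),
                        np.ascontiguousarray(theta), self.C, self.M, out)
        return out

    def person_loglik(self, alpha: np.ndarray, delta: np.ndarray,
                      tau: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Total log-likelihood per person at the given constrained values."""
        tau_cs = np.zeros((self.I, self.C + 1))
        tau_cs[:, 1:] = np.cumsum(tau, axis=1)
        out = np.empty(self.J)
        _person_ll_kernel(self.z, self.obs, self.trait, alpha, delta,
                          np.ascontiguousarray(tau_cs),
                          np.ascontiguousarray(theta), self.C, self.M, out)
        return out

    def item_blocks(self) -> list:
        """Index vectors tying each item's (log alpha, location, thresholds)
        together for the block-diagonal HMC metric."""
        out = []
        for i in range(self.I):
            idx = [i, self.I + i] + [2 * self.I + i * self.C + k
                                     for k in range(self.C)]
            out.append(np.asarray(idx, dtype=int))
        return out

    def reflected(self, q: np.ndarray, d: int) -> np.ndarray:
        """Involutive reflection proposal for dimension d: negate theta_d
        (via eta column d and the correlation parameters coupling d to the
        other dimensions), neutral-item locations on d, and the covariate
        effects on d.  Bounded locations keep their sign (in a reflected
        mode they sit near the zero boundary anyway), so this is a
        mode-jumping Metropolis proposal, exact only for unanchored
        dimensions.  The map is a coordinate sign flip (orthogonal
        involution), so it also transports gradients covariantly."""
        qn = q.copy()
        vd = qn[self._s[1]]
        flip_items = (self.trait == d) & ~self.bounded
        vd[flip_items] *= -1
        eta = qn[self._s[3]].reshape(self.J, self.D)
        eta[:, d] *= -1
        if self.K:
            y = qn[self._s[4]]
            for k, (i, j) in enumerate(self.cpc_pairs):
                if (i == d) != (j == d):
                    y[k] *= -1
        if self.P:
            qn[self._s[5]].reshape(self.P, self.D)[:, d] *= -1
        return qn

    def pointwise_ll(self, q: np.ndarray) -> np.ndarray:
        _, _, tau, theta, alpha, delta = self.unpack(q)
        tau_cs = np.zeros((self.I, self.C + 1))
        tau_cs[:, 1:] = np.cumsum(tau, axis=1)
        out = np.empty(int(self.obs.sum()))
        _pointwise_ll_kernel(self.z, self.obs, self.trait, alpha, delta,
                             np.ascontiguousarray(tau_cs),
                             np.ascontiguousarray(theta),
                             self.C, self.M, out)
        return out


# ---------------------------------------------------------------------------
# HMC driver
# ---------------------------------------------------------------------------


class _DualAveraging:
    """Nesterov dual averaging of the step size toward a target acceptance."""

    def __init__(self, eps0: float, target: float, gamma: float = 0.05,
                 t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.m = 0
        self.hbar = 0.0
        self.log_eps = np.log(eps0)
        self.log_eps_bar = np.log(eps0)

    def restart(self, eps: float) -> None:
        self.mu = np.log(10.0 * eps)
        self.m = 0
        self.hbar = 0.0
        self.log_eps = np.log(eps)
        self.log_eps_bar = np.log(eps)

    def update(self, accept_stat: float) -> float:
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.hbar = (1 - frac) * self.hbar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.hbar
        eta = self.m ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1 - eta) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def eps_bar(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Welford:
    """Running diagonal variance plus dense covariance for selected blocks."""

    def __init__(self, n: int, blocks: Sequence[np.ndarray] = ()):
        self.count = 0
        self.mean = np.zeros(n)
        self.m2 = np.zeros(n)
        self.blocks = [np.asarray(b) for b in blocks]
        self.block_m2 = [np.zeros((b.size, b.size)) for b in self.blocks]

    def add(self, x: np.ndarray) -> None:
        self.count += 1
        d_pre = x - self.mean
        self.mean += d_pre / self.count
        d_post = x - self.mean
        self.m2 += d_pre * d_post
        for idx, m2 in zip(self.blocks, self.block_m2):
            m2 += np.outer(d_pre[idx], d_post[idx])

    def variance(self) -> np.ndarray:
        if self.count < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.count - 1)
        # Stan-style regularization toward a small constant
        w = self.count / (self.count + 5.0)
        return w * var + (1 - w) * 1e-3

    def block_covariances(self) -> list:
        out = []
        w = self.count / (self.count + 5.0)
        for idx, m2 in zip(self.blocks, self.block_m2):
            if self.count < 2:
                out.append(np.eye(idx.size))
            else:
                cov = m2 / (self.count - 1)
                out.append(w * cov + (1 - w) * 1e-3 * np.eye(idx.size))
        return out


class _Metric:
    """Block-diagonal HMC metric: dense per-item blocks (log alpha, location,
    thresholds are strongly correlated a posteriori), diagonal elsewhere.

    All blocks have equal size, so they are stacked into one (I, B, B)
    tensor and applied with a single gather / einsum / scatter.
    """

    def __init__(self, n: int, blocks: Sequence[np.ndarray] = ()):
        self.n = n
        self.blocks = [np.asarray(b) for b in blocks]
        self.idx = (np.stack(self.blocks) if self.blocks
                    else np.zeros((0, 0), dtype=int))            # (I, B)
        self.in_block = np.zeros(n, dtype=bool)
        self.in_block[self.idx.ravel()] = True
        self.diag = np.ones(n)                      # posterior variances
        nb, B = self.idx.shape
        self.cov = np.broadcast_to(np.eye(B), (nb, B, B)).copy()
        self._refresh()

    def _refresh(self) -> None:
        self.chol = np.linalg.cholesky(self.cov) if self.idx.size else None
        self.sqrt_diag = np.sqrt(self.diag)

    def set_estimates(self, diag_var: np.ndarray, block_covs: list) -> None:
        self.diag = diag_var
        if block_covs:
            self.cov = np.stack(block_covs)
        self._refresh()

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        zeta = rng.standard_normal(self.n)
        p = zeta / self.sqrt_diag
        if self.idx.size:
            # p_block = L^{-T} zeta  with cov = L L^T
            sol = np.linalg.solve(np.swapaxes(self.chol, 1, 2),
                                  zeta[self.idx][:, :, None])
            p[self.idx] = sol[:, :, 0]
        return p

    def velocity(self, p: np.ndarray) -> np.ndarray:
        v = self.diag * p
        if self.idx.size:
            v[self.idx] = np.einsum("ibc,ic->ib", self.cov, p[self.idx])
        return v

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self.velocity(p))


def _find_initial_eps(post: _Posterior, q: np.ndarray, metric: _Metric,
                      rng: np.random.Generator) -> float:
    """Double/halve eps until one leapfrog step has acceptance near 0.5."""
    eps = 0.1
    lp, grad = post.logp_grad(q)
    p = metric.sample_momentum(rng)
    h0 = -lp + metric.kinetic(p)

    def one_step(eps: float) -> float:
        p1 = p + 0.5 * eps * grad
        q1 = q + eps * metric.velocity(p1)
        lp1, g1 = post.logp_grad(q1)
        if not np.isfinite(lp1):
            return -np.inf
        p1 = p1 + 0.5 * eps * g1
        return h0 - (-lp1 + metric.kinetic(p1))

    diff = one_step(eps)
    direction = 1 if diff > np.log(0.5) else -1
    for _ in range(30):
        eps = eps * (2.0 ** direction)
        diff = one_step(eps)
        if (direction == 1 and diff <= np.log(0.5)) or \
           (direction == -1 and diff >= np.log(0.5)):
            break
    return max(eps, 1e-8)


def _init_chain(post: _Posterior, rng: np.random.Generator) -> np.ndarray:
    """Random initial values on the unconstrained scale.

    Starts are centred on the priors with moderate jitter: scrambled
    high-dimensional trait starts can strand a chain in a self-consistent
    but inferior (theta, item) configuration, while neutral starts let the
    data pull all blocks into the dominant basin during warmup."""
    I, J, D, C = post.I, post.J, post.D, post.C
    ua = 0.25 * rng.standard_normal(I)
    vd = 0.5 * rng.standard_normal(I)
    tau = post.tau_mean + 0.25 * rng.standard_normal((I, C))
    eta = 0.5 * rng.standard_normal((J, D))
    y = 0.2 * rng.standard_normal(post.K)
    beta = 0.1 * rng.standard_normal(post.P * post.D)
    return np.concatenate([ua, vd, tau.ravel(), eta.ravel(), y, beta])


# ---------------------------------------------------------------------------
# posterior fit container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorFit:
    """Posterior draws, diagnostics and summaries from one MCMC run.

    ``draws`` maps parameter family -> array with leading axes
    (chain, retained draw); ``rhat`` holds the matching per-parameter
    Gelman-Rubin factors; ``pointwise_loglik`` is (total draws, n observed
    cells) for WAIC/LOO.
    """

    draws: Dict[str, np.ndarray]
    rhat: Dict[str, np.ndarray]
    converged: bool
    max_rhat: float
    estimates: Dict[str, np.ndarray]
    ses: Dict[str, np.ndarray]
    ci95: Dict[str, np.ndarray]
    pointwise_loglik: Optional[np.ndarray]
    n_divergent: int
    accept_rate: float
    trait: np.ndarray
    dir_code: np.ndarray
    n_covariates: int
    config: McmcConfig

    @property
    def n_traits(self) -> int:
        return int(self.trait.max()) + 1

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains merged: (chains*draws, ...)."""
        x = self.draws[name]
        return x.reshape((-1,) + x.shape[2:])

    def summary(self, include_theta: bool = False) -> pd.DataFrame:
        rows = []

        def emit(family, labels, est, se, lo, hi, rh):
            for lab, e, s, l, h, r in zip(labels, est, se, lo, hi, rh):
                rows.append((f"{family}[{lab}]", e, s, l, h, r))

        I = len(self.trait)
        items = [str(i + 1) for i in range(I)]
        for fam in ("alpha", "delta"):
            emit(fam, items, self.estimates[fam], self.ses[fam],
                 self.ci95[fam][0], self.ci95[fam][1], self.rhat[fam])
        C = self.draws["tau"].shape[-1]
        emit("tau", [f"{i + 1},{k + 1}" for i in range(I) for k in range(C)],
             self.estimates["tau"].ravel(), self.ses["tau"].ravel(),
             self.ci95["tau"][0].ravel(), self.ci95["tau"][1].ravel(),
             self.rhat["tau"].ravel())
        if "beta" in self.draws:
            P, D = self.estimates["beta"].shape
            emit("beta", [f"x{p + 1},{d + 1}" for p in range(P) for d in range(D)],
                 self.estimates["beta"].ravel(), self.ses["beta"].ravel(),
                 self.ci95["beta"][0].ravel(), self.ci95["beta"][1].ravel(),
                 self.rhat["beta"].ravel())
        D = self.n_traits
        if D > 1:
            labs = [f"{d + 1},{e + 1}" for d in range(D) for e in range(d + 1, D)]
            idx = [(d, e) for d in range(D) for e in range(d + 1, D)]
            emit("omega", labs,
                 [self.estimates["omega"][d, e] for d, e in idx],
                 [self.ses["omega"][d, e] for d, e in idx],
                 [self.ci95["omega"][0][d, e] for d, e in idx],
                 [self.ci95["omega"][1][d, e] for d, e in idx],
                 [self.rhat["omega"][d, e] for d, e in idx])
        if include_theta:
            J = self.estimates["theta"].shape[0]
            emit("theta", [f"{j + 1},{d + 1}" for j in range(J) for d in range(D)],
                 self.estimates["theta"].ravel(), self.ses["theta"].ravel(),
                 self.ci95["theta"][0].ravel(), self.ci95["theta"][1].ravel(),
                 self.rhat["theta"].ravel())
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se",
                                           "ci2.5", "ci97.5", "rhat"])

    def trait_scores(self) -> pd.DataFrame:
        est = self.estimates["theta"]
        se = self.ses["theta"]
        J, D = est.shape
        out = {"person": np.arange(1, J + 1)}
        for d in range(D):
            out[f"theta{d + 1}"] = est[:, d]
            out[f"theta{d + 1}_se"] = se[:, d]
        return pd.DataFrame(out)

    def save(self, out_dir: Union[str, Path]) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        arrays = {f"draws_{k}": v for k, v in self.draws.items()}
        if self.pointwise_loglik is not None:
            arrays["pointwise_loglik"] = self.pointwise_loglik
        arrays["trait"] = self.trait
        arrays["dir_code"] = self.dir_code
        arrays["meta"] = np.array([
            float(self.converged), self.max_rhat, float(self.n_divergent),
            self.accept_rate, float(self.n_covariates),
        ])
        np.savez_compressed(out / "draws.npz", **arrays)
        self.summary().to_csv(out / "summary.csv", index=False)
        self.trait_scores().to_csv(out / "trait_scores.csv", index=False)
        return out


def load_fit(fit_dir: Union[str, Path]) -> Dict[str, np.ndarray]:
    """Load the arrays written by :meth:`PosteriorFit.save`."""
    with np.load(Path(fit_dir) / "draws.npz") as z:
        return {k: z[k] for k in z.files}


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def gelman_rubin(draws: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``draws`` is (chains, n).  R-hat = sqrt(((n-1)/n * W + B/n) / W) with W
    the mean within-chain variance and B/n the variance of the chain means
    (sample variances, n-1 denominator).  Zero within-chain variance makes
    the ratio undefined and is reported as ``inf`` (treated as nonconverged).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 2:
        raise ValueError("need at least 2 chains with at least 2 draws each")
    return float(_rhat_nd(draws[:, :, None])[0])


def _rhat_nd(x: np.ndarray) -> np.ndarray:
    """Vectorized PSRF over trailing axes of (chains, n, ...)."""
    n = x.shape[1]
    W = x.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = x.mean(axis=1).var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(((n - 1) / n * W + B_over_n) / W)
    r = np.where(W <= 0, np.inf, r)
    return np.atleast_1d(r)


def covariate_significance(fitted: PosteriorFit) -> np.ndarray:
    """(P, D) booleans: 95% credible interval of beta_pd excludes zero."""
    if "beta" not in fitted.draws:
        raise ValueError("model was fitted without covariates")
    lo, hi = fitted.ci95["beta"]
    return (lo > 0) | (hi < 0)


# ---------------------------------------------------------------------------
# main fitting routine
# ---------------------------------------------------------------------------


def fit(model: MggumModel, config: Optional[McmcConfig] = None) -> PosteriorFit:
    """Sample the posterior and assemble summaries and diagnostics.

    Runs ``n_chains`` independent chains (HMC over all continuous
    parameters, plus involutive Metropolis moves for the discrete
    sign-symmetries of the unfolding likelihood), discards warmup, computes
    R-hat for every scalar parameter, posterior means/SDs/95% intervals,
    and the pointwise log-likelihood matrix over non-missing cells.
    """
    if config is None:
        config = McmcConfig()
    post = _Posterior(model)
    J, I, D, C = post.J, post.I, post.D, post.C
    P = model.n_covariates
    n_keep = config.n_keep
    W = config.n_burnin
    w1, w2, w3 = max(1, W // 10), W // 2, (9 * W) // 10

    draws = {
        "alpha": np.empty((config.n_chains, n_keep, I)),
        "delta": np.empty((config.n_chains, n_keep, I)),
        "tau": np.empty((config.n_chains, n_keep, I, C)),
        "theta": np.empty((config.n_chains, n_keep, J, D)),
        "omega": np.empty((config.n_chains, n_keep, D, D)),
    }
    if P:
        draws["beta"] = np.empty((config.n_chains, n_keep, P, D))
    n_obs = model.responses.n_observed
    ll_store = (np.empty((config.n_chains, n_keep, n_obs))
                if config.pointwise_loglik else None)

    n_div_total = 0
    acc_total = 0.0
    acc_count = 0

    for chain in range(config.n_chains):
        rng = np.random.default_rng([int(config.seed), 1000 + chain])
        q = _init_chain(post, rng)

        lp, grad = post.logp_grad(q)
        for _ in range(20):
            if np.isfinite(lp):
                break
            q = _init_chain(post, rng)
            lp, grad = post.logp_grad(q)
        if not np.isfinite(lp):
            raise RuntimeError(
                "sampler initialization failed: log-posterior not finite after "
                "20 random restarts; check the data and priors"
            )

        blocks = post.item_blocks()
        unanchored_dims = np.where(~model.anchored_dims())[0]
        refl_refs: Dict[int, np.ndarray] = {}
        metric = _Metric(post.n_q, blocks)
        ramp = max(1, W // 4)
        post.lik_weight = 1.0 / ramp
        lp, grad = post.logp_grad(q)
        eps = _find_initial_eps(post, q, metric, rng)
        da = _DualAveraging(eps, config.target_accept)
        welford = _Welford(post.n_q, blocks)

        for it in range(config.n_iterations):
            warm = it < W
            w_target = min(1.0, (it + 1) / ramp)
            if post.lik_weight != w_target:
                post.lik_weight = w_target
                lp, grad = post.logp_grad(q)
            # --- HMC update of (item params, theta, omega) ----------------
            L = int(rng.integers(config.max_leapfrog // 2, config.max_leapfrog + 1))
            p0 = metric.sample_momentum(rng)
            h0 = -lp + metric.kinetic(p0)
            qn, pn, lpn, gn = q, p0, lp, grad
            pn = pn + 0.5 * eps * gn
            diverged = False
            for step in range(L):
                qn = qn + eps * metric.velocity(pn)
                lpn, gn = post.logp_grad(qn)
                if not np.isfinite(lpn):
                    diverged = True
                    break
                if step < L - 1:
                    pn = pn + eps * gn
            if not diverged:
                pn = pn + 0.5 * eps * gn
                h1 = -lpn + metric.kinetic(pn)
                ediff = h0 - h1
                if not np.isfinite(ediff) or ediff < -1000.0:
                    diverged = True
            if diverged:
                accept_stat = 0.0
                n_div_total += 1
            else:
                accept_stat = min(1.0, float(np.exp(min(ediff, 0.0))))
                if np.log(rng.random()) < ediff:
                    q, lp, grad = qn, lpn, gn
            if warm:
                eps = da.update(accept_stat)
            else:
                acc_total += accept_stat
                acc_count += 1

            # --- itemwise location sign-flip Metropolis -------------------
            # A weakly informed item's location posterior can be bimodal at
            # ~(+/-)|delta| (the response curve is symmetric about delta);
            # this involutive proposal mixes the two sub-modes directly.
            # Only neutral items move: bounded priors pin the sign.
            # (the |.|-threshold proposal sets are themselves flip-invariant,
            # so restricting to non-trivial flips preserves reversibility)
            flip_round = it % 2 == 0
            if flip_round and np.any(~post.bounded):
                _, _, tau_c, theta_c, alpha_c, delta_c = post.unpack(q)
                movable = ~post.bounded & (np.abs(delta_c) > 0.3)
                if np.any(movable):
                    cur_ill = post.item_loglik(alpha_c, delta_c, tau_c, theta_c)
                    flip_delta = np.where(movable, -delta_c, delta_c)
                    prop_ill = post.item_loglik(alpha_c, flip_delta, tau_c, theta_c)
                    acc_flip = movable & (
                        np.log(rng.random(I)) < post.lik_weight * (prop_ill - cur_ill))
                    if np.any(acc_flip):
                        q[post._s[1]][acc_flip] *= -1.0   # neutral: v IS delta
                        lp, grad = post.logp_grad(q)

            # --- personwise trait sign-flip Metropolis --------------------
            # An extreme respondent (e.g., one who disagrees with every
            # item) has a bimodal trait posterior: both tails place them far
            # from every item location.  Persons are independent given the
            # items, so one vectorized involutive proposal per dimension
            # mixes those sub-modes directly.
            if flip_round:
                d_flip = (it // 2) % D
                _, _, tau_c, theta_c, alpha_c, delta_c = post.unpack(q)
                cur_pll = post.person_loglik(alpha_c, delta_c, tau_c, theta_c)
                theta_f = np.ascontiguousarray(theta_c)
                theta_f = theta_f.copy()
                theta_f[:, d_flip] *= -1
                prop_pll = post.person_loglik(alpha_c, delta_c, tau_c, theta_f)
                # the flip in theta-space maps to eta' = (theta' - mu) L^{-T}
                # (unit-Jacobian linear involution); the prior ratio is the
                # standard-normal ratio of the eta rows
                Lom = post.chol_omega(q)
                mu_now = post.mean_of(q)
                eta_cur = q[post._s[3]].reshape(J, D)
                eta_prop = solve_triangular(Lom, (theta_f - mu_now).T,
                                            lower=True).T
                dprior = -0.5 * (np.sum(eta_prop ** 2, axis=1)
                                 - np.sum(eta_cur ** 2, axis=1))
                acc_p = ((np.abs(theta_c[:, d_flip]) > 0.5)
                         & (np.log(rng.random(J))
                            < post.lik_weight * (prop_pll - cur_pll) + dprior))
                if np.any(acc_p):
                    eta_cur[acc_p] = eta_prop[acc_p]
                    lp, grad = post.logp_grad(q)

            # --- warmup mode-jumping: per-dimension reflection proposals --
            if warm and it % 25 == 24:
                for d in range(D):
                    qf = post.reflected(q, d)
                    lpf, gf = post.logp_grad(qf)
                    if np.isfinite(lpf) and np.log(rng.random()) < lpf - lp:
                        q, lp, grad = qf, lpf, gf

            # --- quotient-space canonicalization of unanchored dims -------
            # For a dimension with no bounded item the reflection is an
            # exact, measure-preserving symmetry: mapping the state back to
            # a fixed side of it leaves the target invariant and stops the
            # chain from wandering between the two mirror-image modes.
            if it + 1 >= w2:
                eta_now = q[post._s[3]].reshape(J, D)
                for d in unanchored_dims:
                    if d not in refl_refs:
                        refl_refs[d] = eta_now[:, d].copy()
                        continue
                    if float(eta_now[:, d] @ refl_refs[d]) < 0:
                        q = post.reflected(q, d)
                        grad = post.reflected(grad, d)

            # --- warmup adaptation windows --------------------------------
            if warm:
                if w1 <= it < w3:
                    welford.add(q)
                if it + 1 == w2 or it + 1 == w3:
                    metric.set_estimates(welford.variance(),
                                         welford.block_covariances())
                    welford = _Welford(post.n_q, blocks)
                    eps = _find_initial_eps(post, q, metric, rng)
                    da.restart(eps)
                if it + 1 == W:
                    eps = da.eps_bar
            else:
                k = it - W
                _, _, tau, theta, alpha, delta = post.unpack(q)
                draws["alpha"][chain, k] = alpha
                draws["delta"][chain, k] = delta
                draws["tau"][chain, k] = tau
                draws["theta"][chain, k] = theta
                draws["omega"][chain, k] = post.omega(q)
                if P:
                    draws["beta"][chain, k] = post.beta_of(q)
                if ll_store is not None:
                    ll_store[chain, k] = post.pointwise_ll(q)

    # --- reflection canonicalization for unanchored dimensions ------------
    # The likelihood is exactly invariant under a joint sign flip of any
    # dimension with no bounded-location item, so each draw is mapped to one
    # fundamental domain of that symmetry (cf. relabeling in mixture models).
    anchored = model.anchored_dims()
    for d in np.where(~anchored)[0]:
        _canonicalize_dimension(draws, model.trait, d)

    rhat = {
        "alpha": _rhat_nd(draws["alpha"]),
        "delta": _rhat_nd(draws["delta"]),
        "tau": _rhat_nd(draws["tau"]),
        "theta": _rhat_nd(draws["theta"]),
    }
    if P:
        rhat["beta"] = _rhat_nd(draws["beta"])
    if D > 1:
        om_r = _rhat_nd(draws["omega"])
        om_r[np.eye(D, dtype=bool)] = 1.0   # fixed unit diagonal
        rhat["omega"] = om_r
    else:
        rhat["omega"] = np.ones((1, 1))
    max_rhat = max(float(np.max(v)) for v in rhat.values())
    converged = bool(max_rhat < config.rhat_threshold)

    estimates, ses, ci95 = {}, {}, {}
    for k, v in draws.items():
        flat = v.reshape((-1,) + v.shape[2:])
        estimates[k] = flat.mean(axis=0)
        ses[k] = flat.std(axis=0, ddof=1)
        ci95[k] = np.quantile(flat, [0.025, 0.975], axis=0)

    pointwise = (ll_store.reshape(-1, n_obs) if ll_store is not None else None)
    return PosteriorFit(
        draws=draws, rhat=rhat, converged=converged, max_rhat=max_rhat,
        estimates=estimates, ses=ses, ci95=ci95, pointwise_loglik=pointwise,
        n_divergent=n_div_total,
        accept_rate=acc_total / max(acc_count, 1),
        trait=model.trait.copy(), dir_code=model.dir_code.copy(),
        n_covariates=P, config=config,
    )


def _canonicalize_dimension(draws: Dict[str, np.ndarray], trait: np.ndarray,
                            d: int) -> None:
    """Per-draw sign canonicalization of one reflection-invariant dimension.

    Each draw's (theta_d, delta on d, beta_.d, omega_d.) is flipped so that
    its theta_d pattern has a positive inner product with a self-consistent
    reference direction (a few fixed-point iterations of 'flip, then update
    the reference as the mean of flipped draws')."""
    X = draws["theta"][:, :, :, d]                      # (chains, keep, J)
    ref = X[0, 0].copy()
    if not np.any(ref):
        return
    s = np.ones(X.shape[:2])
    for _ in range(3):
        dots = np.tensordot(X, ref, axes=([2], [0]))
        s = np.where(dots < 0, -1.0, 1.0)
        ref = (s[:, :, None] * X).mean(axis=(0, 1))
    items_d = trait == d
    draws["theta"][:, :, :, d] *= s[:, :, None]
    draws["delta"][:, :, items_d] = draws["delta"][:, :, items_d] * s[:, :, None]
    if "beta" in draws:
        draws["beta"][:, :, :, d] *= s[:, :, None]
    draws["omega"][:, :, d, :] *= s[:, :, None]
    draws["omega"][:, :, :, d] *= s[:, :, None]         # diagonal flips twice


# ---------------------------------------------------------------------------
# delimited-text input
# ---------------------------------------------------------------------------


def read_responses(path: Union[str, Path]) -> ResponseMatrix:
    """Read a persons x items CSV (optional leading 'person' column; NA or
    empty cells mark missing responses)."""
    df = pd.read_csv(path)
    if df.columns[0].lower() == "person":
        df = df.drop(columns=df.columns[0])
    vals = df.to_numpy(dtype=float)
    mask = np.isnan(vals)
    vals = np.where(mask, 0, vals).astype(int)
    return ResponseMatrix(values=vals, missing_mask=mask)


def read_itemmap(path: Union[str, Path]) -> ItemBank:
    """Read an item map CSV: columns item, trait (1-based), direction, plus
    optional generating alpha/delta/tau columns used for recovery scoring."""
    df = pd.read_csv(path)
    need = {"item", "trait", "direction"}
    if not need <= set(df.columns):
        raise ValueError(f"item map must contain columns {sorted(need)}")
    I = len(df)
    tau_cols = sorted([c for c in df.columns if c.startswith("tau")],
                      key=lambda c: int(c[3:]))
    has_truth = "alpha" in df.columns and "delta" in df.columns and tau_cols
    return ItemBank(
        dimension=df["trait"].to_numpy(dtype=int) - 1,
        alpha=df["alpha"].to_numpy(dtype=float) if has_truth else np.ones(I),
        delta=df["delta"].to_numpy(dtype=float) if has_truth else np.zeros(I),
        tau=(df[tau_cols].to_numpy(dtype=float) if tau_cols
             else np.full((I, 1), -1.0)),
        direction=df["direction"].astype(str).to_numpy(),
    )


def read_covariates(path: Union[str, Path]) -> np.ndarray:
    """Read a persons x covariates CSV (optional leading 'person' column)."""
    df = pd.read_csv(path)
    if df.columns[0].lower() == "person":
        df = df.drop(columns=df.columns[0])
    X = df.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing covariate values are unsupported")
    return X
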