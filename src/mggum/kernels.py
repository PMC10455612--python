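"""Core response-process kernels for the generalized graded unfolding model.

The GGUM is an ideal-point (unfolding) item response model: the probability of
endorsing an item peaks when a respondent's latent trait level matches the
item's location delta and falls off symmetrically with distance on either
side.  For an item with discrimination ``alpha``, location ``delta`` and
subjective response category thresholds ``tau_1..tau_C`` (``tau_0 = 0``
implicitly), the probability of observed category ``z`` in ``0..C`` is

    P(Z = z | theta) proportional to
        exp(alpha * (z * (theta - delta) - S_z))
      + exp(alpha * ((M - z) * (theta - delta) - S_z))

with ``S_z = sum_{k<=z} tau_k`` and ``M = 2C + 1``, normalized over
``z = 0..C``.  The multidimensional extension (between-item simple structure:
every item loads exactly one trait) replaces ``alpha*(theta - delta)`` with
the weighted Euclidean distance ``sqrt(sum_d alpha_d^2 (theta_d - delta_d)^2)``
and the threshold term with ``psi_k = sum_d alpha_d tau_k``; under simple
structure this reduces exactly to the unidimensional kernel on the loading
dimension (the response function is symmetric about delta, so the sign of
``theta - delta`` is irrelevant).

Everything here is computed in log space with max-subtraction so that
exponents as large as ``|alpha * (theta - delta)| ~ 50`` are safe.

All containers are thin, validated dataclasses around numpy arrays; trait
(dimension) indices are stored 0-based internally and written 1-based in any
delimited-text output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ResponseScale",
    "Item",
    "ItemBank",
    "PersonSample",
    "StructuralModel",
    "ResponseMatrix",
    "ggum_category_probabilities",
    "mggum_category_probabilities",
    "latent_mean",
    "joint_log_likelihood",
    "pointwise_log_likelihood",
]

DIRECTIONS = ("negative", "neutral", "positive")


@dataclass(frozen=True)
class ResponseScale:
    """Response scale with C + 1 ordered options; M = 2C + 1 is derived."""

    C: int

    def __post_init__(self) -> None:
        if int(self.C) != self.C or self.C < 1:
            raise ValueError(f"C must be an integer >= 1, got {self.C!r}")
        object.__setattr__(self, "C", int(self.C))

    @property
    def M(self) -> int:
        return 2 * self.C + 1

    @property
    def n_options(self) -> int:
        return self.C + 1

    @classmethod
    def from_options(cls, n_options: int) -> "ResponseScale":
        return cls(C=n_options - 1)


@dataclass(frozen=True)
class Item:
    """A single item: loading dimension (0-based), alpha, delta, tau, label."""

    dimension: int
    alpha: float
    delta: float
    tau: np.ndarray
    direction: str = "neutral"

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau", np.atleast_1d(np.asarray(self.tau, dtype=float)))
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")


@dataclass
class ItemBank:
    """Per-item parameters under between-item simple structure.

    Each item loads exactly one trait (``dimension``, 0-based).  ``tau`` is an
    ``(I, C)`` array of subjective response category thresholds.  ``direction``
    labels (negative / neutral / positive) drive the location priors at
    estimation time.
    """

    dimension: np.ndarray
    alpha: np.ndarray
    delta: np.ndarray
    tau: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.dimension = np.asarray(self.dimension, dtype=int)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.tau = np.atleast_2d(np.asarray(self.tau, dtype=float))
        self.direction = np.asarray(self.direction, dtype=object)
        n = self.n_items
        for name in ("alpha", "delta", "direction"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length {n}")
        if self.tau.shape[0] != n:
            raise ValueError("tau must have one row per item")
        if np.any(self.alpha <= 0):
            raise ValueError("all discriminations alpha must be positive")
        if self.dimension.min(initial=0) < 0:
            raise ValueError("dimension indices are 0-based and must be >= 0")
        bad = set(self.direction) - set(DIRECTIONS)
        if bad:
            raise ValueError(f"unknown direction labels: {bad}")

    @property
    def n_items(self) -> int:
        return len(self.dimension)

    @property
    def n_traits(self) -> int:
        return int(self.dimension.max()) + 1

    @property
    def C(self) -> int:
        return self.tau.shape[1]

    def __getitem__(self, i: int) -> Item:
        return Item(
            dimension=int(self.dimension[i]),
            alpha=float(self.alpha[i]),
            delta=float(self.delta[i]),
            tau=self.tau[i].copy(),
            direction=str(self.direction[i]),
        )


@dataclass
class PersonSample:
    """Latent traits theta (J x D) and optional covariates X (J x P)."""

    theta: np.ndarray
    X: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if self.X is not None:
            self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
            if self.X.shape[0] != self.theta.shape[0]:
                raise ValueError("theta and X must have the same number of rows")
            if np.isnan(self.X).any():
                raise ValueError("covariates X may not contain missing values")

    @property
    def n_persons(self) -> int:
        return self.theta.shape[0]

    @property
    def n_traits(self) -> int:
        return self.theta.shape[1]


@dataclass
class StructuralModel:
    """Latent regression theta = X beta + eps, eps ~ N(0, sigma2 * omega).

    ``omega`` is a correlation matrix (unit diagonal, positive semi-definite); the
    residual scale is fixed at 1 per dimension for identification, so
    ``sigma2`` defaults to 1.
    """

    beta: np.ndarray
    omega: np.ndarray
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        om = self.omega
        if om.shape[0] != om.shape[1]:
            raise ValueError("omega must be square")
        if not np.allclose(om, om.T, atol=1e-10):
            raise ValueError("omega must be symmetric")
        if not np.allclose(np.diag(om), 1.0, atol=1e-10):
            raise ValueError("omega must have a unit diagonal")
        if np.linalg.eigvalsh(om).min() < -1e-10:
            # singular omega (perfectly correlated traits) is a legitimate
            # generating configuration; only indefinite matrices are invalid
            raise ValueError("omega must be positive semi-definite")


@dataclass
class ResponseMatrix:
    """J x I integer categories in 0..C with a boolean missingness mask."""

    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values))
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask must match the shape of values")
        obs = self.values[~self.missing_mask]
        if obs.size and (np.any(obs != np.asarray(obs, dtype=int)) or obs.min() < 0):
            raise ValueError("non-missing responses must be nonnegative integers")
        self.values = self.values.astype(int)

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def n_observed(self) -> int:
        return int((~self.missing_mask).sum())

    def validate_scale(self, scale: ResponseScale) -> None:
        obs = self.values[~self.missing_mask]
        if obs.size and obs.max() > scale.C:
            raise ValueError(
                f"response category {obs.max()} outside 0..{scale.C}"
            )


# ---------------------------------------------------------------------------
# probability kernels
# ---------------------------------------------------------------------------


def _log_numerators(x: np.ndarray, alpha: np.ndarray, tau_cumsum: np.ndarray,
                    scale: ResponseScale) -> np.ndarray:
    """Log numerator of each category, shape (..., C+1).

    ``x`` is the (signed or absolute) discrimination-free distance theta-delta
    broadcast against ``alpha``; ``tau_cumsum`` holds S_z = sum_{k<=z} tau_k
    for z = 0..C (so its last axis has length C+1 and starts at 0).
    """
    z = np.arange(scale.C + 1, dtype=float)
    ax = np.asarray(alpha, dtype=float)[..., None] * np.asarray(x, dtype=float)[..., None]
    s = np.asarray(alpha, dtype=float)[..., None] * tau_cumsum
    t1 = z * ax - s
    t2 = (scale.M - z) * ax - s
    return np.logaddexp(t1, t2)


def _tau_cumsum(tau: np.ndarray) -> np.ndarray:
    """S_z for z=0..C from tau rows (tau_0 = 0 implicit): shape (..., C+1)."""
    tau = np.asarray(tau, dtype=float)
    zeros = np.zeros(tau.shape[:-1] + (1,))
    return np.concatenate([zeros, np.cumsum(tau, axis=-1)], axis=-1)


def ggum_category_probabilities(theta: float, alpha: float, delta: float,
                                tau: np.ndarray, scale: ResponseScale) -> np.ndarray:
    """Unidimensional GGUM category probabilities P(Z=z|theta), z = 0..C.

    Overflow-safe (log-sum-exp); raises on non-positive ``alpha`` or a
    threshold vector whose length is not C.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if tau.shape[-1] != scale.C:
        raise ValueError(f"tau must have length C={scale.C}, got {tau.shape[-1]}")
    lognum = _log_numerators(np.asarray(theta) - delta, alpha, _tau_cumsum(tau), scale)
    return np.exp(lognum - logsumexp(lognum, axis=-1, keepdims=True))


def mggum_category_probabilities(theta_row: np.ndarray, item: Item,
                                 scale: ResponseScale) -> np.ndarray:
    """MGGUM category probabilities for one person and one item.

    Uses the multidimensional kernel: distance term
    ``sqrt(sum_d alpha_d^2 (theta_d - delta_d)^2)`` and threshold sums
    ``psi_k = sum_d alpha_d tau_k``.  Under between-item simple structure
    (alpha_d = 0 except on the loading dimension) this equals the
    unidimensional kernel applied on the loading dimension.
    """
    theta_row = np.atleast_1d(np.asarray(theta_row, dtype=float))
    if item.dimension >= theta_row.shape[-1]:
        raise ValueError("item loading dimension exceeds the length of theta_row")
    if item.alpha <= 0:
        raise ValueError("item has all-zero (non-positive) loadings")
    if item.tau.shape[-1] != scale.C:
        raise ValueError(f"tau must have length C={scale.C}")
    # simple structure: only the loading dimension contributes to the distance
    diff = theta_row[..., item.dimension] - item.delta
    dist = np.sqrt(item.alpha ** 2 * diff ** 2)
    # exponents are dist-based: z*dist - sum psi_k, with psi_k = alpha * tau_k
    psi_cumsum = item.alpha * _tau_cumsum(item.tau)
    z = np.arange(scale.C + 1, dtype=float)
    t1 = z * dist[..., None] - psi_cumsum
    t2 = (scale.M - z) * dist[..., None] - psi_cumsum
    lognum = np.logaddexp(t1, t2)
    return np.exp(lognum - logsumexp(lognum, axis=-1, keepdims=True))


def latent_mean(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Systematic part of the latent regression: (J x P) @ (P x D)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    if X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"shape mismatch: X has {X.shape[1]} covariates, beta has {beta.shape[0]} rows"
        )
    return X @ beta


def _cell_log_probabilities(responses: ResponseMatrix, items: ItemBank,
                            persons: PersonSample, scale: ResponseScale) -> np.ndarray:
    """(J, I) log P[Z_ij = z_ij | theta_j]; entries for missing cells are 0."""
    responses.validate_scale(scale)
    if items.C != scale.C:
        raise ValueError("item bank tau width does not match the response scale")
    if responses.n_items != items.n_items:
        raise ValueError("responses and item bank disagree on the number of items")
    if persons.n_traits < items.n_traits:
        raise ValueError("persons have fewer trait dimensions than the item bank uses")
    theta_load = persons.theta[:, items.dimension]        # (J, I)
    x = theta_load - items.delta[None, :]
    lognum = _log_numerators(x, items.alpha[None, :], _tau_cumsum(items.tau)[None, :, :], scale)
    logdenom = logsumexp(lognum, axis=-1)
    z = responses.values.copy()
    z[responses.missing_mask] = 0
    picked = np.take_along_axis(lognum, z[:, :, None], axis=-1)[:, :, 0]
    out = picked - logdenom
    out[responses.missing_mask] = 0.0
    return out


def pointwise_log_likelihood(responses: ResponseMatrix, items: ItemBank,
                             persons: PersonSample, scale: ResponseScale) -> np.ndarray:
    """Per-cell log-likelihood matrix (J, I); missing cells are exactly 0."""
    return _cell_log_probabilities(responses, items, persons, scale)


def joint_log_likelihood(responses: ResponseMatrix, items: ItemBank,
                         persons: PersonSample, scale: ResponseScale) -> float:
    """Sum of log category probabilities over non-missing cells.

    Missing cells contribute zero, the ignorable-likelihood treatment valid
    under missingness completely at random.
    """
    return float(_cell_log_probabilities(responses, items, persons, scale).sum())
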