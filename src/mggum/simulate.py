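"""Synthetic data generation for MGGUM simulation studies.

The generator reproduces the classic unfolding-model recovery design: item
discriminations alpha ~ U(0.5, 2), locations delta ~ U(-2, 2), thresholds tau
from disjoint uniforms (U(-3, -1) for 2 response options; U(-3.5, -2.5),
U(-2.5, -1.5), U(-1.5, -0.5) for 4 options), persons and covariates jointly
multivariate normal with zero means, unit variances, a common between-trait
correlation, zero between-covariate correlations, and a common trait-covariate
correlation.  Responses are drawn cell-wise from the GGUM category
probabilities; missingness is completely at random with an exact cell count.

Items are assigned to traits in contiguous blocks (items 1..m load trait 1,
m+1..2m trait 2, ...); any fixed assignment is statistically equivalent under
between-item simple structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .estimate import classify_item_direction
from .kernels import (
    ItemBank,
    PersonSample,
    ResponseMatrix,
    ResponseScale,
    StructuralModel,
    _log_numerators,
    _tau_cumsum,
)

__all__ = [
    "SimulationCondition",
    "draw_item_parameters",
    "draw_persons_and_covariates",
    "generate_responses",
    "apply_missingness",
    "simulate_dataset",
    "SimulatedDataset",
    "write_dataset",
]

# tau generating intervals keyed by the number of response options
_TAU_INTERVALS = {
    2: [(-3.0, -1.0)],
    4: [(-3.5, -2.5), (-2.5, -1.5), (-1.5, -0.5)],
}


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design.

    Defaults correspond to a mid-grid recovery condition; every factor level
    used in the studies (sample size 200/500/1000, 2 or 5 traits, 5 or 10
    items per trait, 2 or 4 response options, 0/0.20 missingness, trait
    correlations 0/0.3/0.5/0.6/0.9/1.0, trait-covariate correlation 0/0.25,
    2 covariates) is reachable through the fields.
    """

    n_persons: int = 500
    n_traits: int = 2
    items_per_trait: int = 5
    n_options: int = 2
    missing_prop: float = 0.0
    trait_cor: float = 0.0
    trait_covariate_cor: float = 0.0
    n_covariates: int = 2
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_options not in _TAU_INTERVALS:
            raise ValueError(
                f"unsupported number of response options {self.n_options}; "
                f"supported: {sorted(_TAU_INTERVALS)}"
            )
        if not (0.0 <= self.missing_prop < 1.0):
            raise ValueError("missing_prop must lie in [0, 1)")
        if abs(self.trait_cor) > 1.0:
            raise ValueError("|trait_cor| must be <= 1")
        if min(self.n_persons, self.n_traits, self.items_per_trait) < 1:
            raise ValueError("n_persons, n_traits and items_per_trait must be >= 1")

    @property
    def n_items(self) -> int:
        return self.n_traits * self.items_per_trait

    @property
    def scale(self) -> ResponseScale:
        return ResponseScale.from_options(self.n_options)

    def joint_correlation(self) -> np.ndarray:
        """Implied (D+P) x (D+P) correlation matrix of (theta, X)."""
        D, P = self.n_traits, self.n_covariates
        R = np.eye(D + P)
        R[:D, :D] = np.full((D, D), self.trait_cor)
        np.fill_diagonal(R[:D, :D], 1.0)
        R[:D, D:] = self.trait_covariate_cor
        R[D:, :D] = self.trait_covariate_cor
        return R

    def true_structure(self) -> StructuralModel:
        """Generating structural parameters implied by the joint MVN.

        With unit-variance independent covariates, the regression of each
        trait on X has coefficients equal to the trait-covariate correlation,
        and the residual variance is 1 - P * rho^2.
        """
        D, P = self.n_traits, self.n_covariates
        rho = self.trait_covariate_cor
        beta = np.full((P, D), rho)
        omega = np.full((D, D), self.trait_cor)
        np.fill_diagonal(omega, 1.0)
        resid = 1.0 - P * rho ** 2
        if resid <= 0:
            raise ValueError("trait_covariate_cor implies non-positive residual variance")
        return StructuralModel(beta=beta, omega=omega, sigma2=resid)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationCondition":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def _as_rng(rng: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def draw_item_parameters(condition: SimulationCondition,
                         rng: Union[int, np.random.Generator, None] = None) -> ItemBank:
    """Draw an item bank from the generating uniforms of the study design."""
    rng = _as_rng(rng)
    I = condition.n_items
    alpha = rng.uniform(0.5, 2.0, size=I)
    delta = rng.uniform(-2.0, 2.0, size=I)
    tau = np.column_stack(
        [rng.uniform(lo, hi, size=I) for lo, hi in _TAU_INTERVALS[condition.n_options]]
    )
    dimension = np.repeat(np.arange(condition.n_traits), condition.items_per_trait)
    direction = np.asarray([classify_item_direction(d) for d in delta], dtype=object)
    return ItemBank(dimension=dimension, alpha=alpha, delta=delta, tau=tau,
                    direction=direction)


def draw_persons_and_covariates(condition: SimulationCondition,
                                rng: Union[int, np.random.Generator, None] = None,
                                n_persons: Optional[int] = None) -> PersonSample:
    """Joint MVN draw of traits and covariates with the stated correlations."""
    rng = _as_rng(rng)
    J = condition.n_persons if n_persons is None else n_persons
    D = condition.n_traits
    R = condition.joint_correlation()
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-10:
        raise ValueError(
            "implied joint correlation matrix of (theta, X) is not positive "
            f"semi-definite (min eigenvalue {eig.min():.4g}):\n{R}"
        )
    # 'eigh' factorization: deterministic and valid for singular matrices
    # (needed when trait_cor = 1 makes the trait block rank-deficient)
    draw = rng.multivariate_normal(np.zeros(R.shape[0]), R, size=J, method="eigh")
    return PersonSample(theta=draw[:, :D], X=draw[:, D:])


def generate_responses(persons: PersonSample, items: ItemBank, scale: ResponseScale,
                       rng: Union[int, np.random.Generator, None] = None) -> ResponseMatrix:
    """Draw each cell categorically from the MGGUM category probabilities."""
    rng = _as_rng(rng)
    theta_load = persons.theta[:, items.dimension]
    x = theta_load - items.delta[None, :]
    lognum = _log_numerators(x, items.alpha[None, :], _tau_cumsum(items.tau)[None, :, :],
                             scale)
    m = lognum.max(axis=-1, keepdims=True)
    p = np.exp(lognum - m)
    cdf = np.cumsum(p, axis=-1)
    cdf /= cdf[:, :, -1:]
    u = rng.random(size=x.shape)
    values = (u[:, :, None] > cdf).sum(axis=-1)
    return ResponseMatrix(values=values)


def apply_missingness(responses: ResponseMatrix, missing_prop: float,
                      rng: Union[int, np.random.Generator, None] = None) -> ResponseMatrix:
    """Mask exactly round(missing_prop * J * I) cells, completely at random."""
    if not (0.0 <= missing_prop < 1.0):
        raise ValueError("missing_prop must lie in [0, 1)")
    if missing_prop == 0.0:
        return ResponseMatrix(values=responses.values.copy(),
                              missing_mask=responses.missing_mask.copy())
    rng = _as_rng(rng)
    J, I = responses.values.shape
    n_missing = int(round(missing_prop * J * I))
    flat = rng.choice(J * I, size=n_missing, replace=False)
    mask = responses.missing_mask.copy().reshape(-1)
    mask[flat] = True
    return ResponseMatrix(values=responses.values.copy(), missing_mask=mask.reshape(J, I))


@dataclass
class SimulatedDataset:
    """A fully generated dataset plus the generating truth for scoring."""

    condition: SimulationCondition
    items: ItemBank
    persons: PersonSample
    structure: StructuralModel
    responses: ResponseMatrix

    @property
    def scale(self) -> ResponseScale:
        return self.condition.scale


def simulate_dataset(condition: SimulationCondition,
                     rng: Union[int, np.random.Generator, None] = None) -> SimulatedDataset:
    """Run the full generating pipeline for one condition.

    The order of draws (items, persons, responses, missingness) is fixed, so a
    given seed reproduces the dataset byte for byte.
    """
    if rng is None:
        rng = condition.seed
    rng = _as_rng(rng)
    items = draw_item_parameters(condition, rng)
    persons = draw_persons_and_covariates(condition, rng)
    responses = generate_responses(persons, items, condition.scale, rng)
    responses = apply_missingness(responses, condition.missing_prop, rng)
    return SimulatedDataset(condition=condition, items=items, persons=persons,
                            structure=condition.true_structure(), responses=responses)


# ---------------------------------------------------------------------------
# delimited-text output
# ---------------------------------------------------------------------------


def _item_labels(n: int) -> list:
    return [f"item{i + 1:02d}" for i in range(n)]


def write_dataset(data: SimulatedDataset, out_dir: Union[str, Path]) -> Path:
    """Write responses, covariates, item map and condition manifest as text.

    Layout: ``responses.csv`` (persons x items, NA = missing),
    ``covariates.csv``, ``itemmap.csv`` (item, trait 1-based, direction, and
    the generating alpha/delta/tau columns for recovery scoring), and
    ``condition.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = _item_labels(data.items.n_items)

    vals = data.responses.values.astype(float)
    vals[data.responses.missing_mask] = np.nan
    resp = pd.DataFrame(vals, columns=labels)
    resp.insert(0, "person", np.arange(1, data.responses.n_persons + 1))
    resp.to_csv(out / "responses.csv", index=False, na_rep="NA", float_format="%.0f")

    if data.persons.X is not None and data.persons.X.shape[1] > 0:
        cov = pd.DataFrame(
            data.persons.X,
            columns=[f"x{p + 1}" for p in range(data.persons.X.shape[1])],
        )
        cov.insert(0, "person", np.arange(1, data.persons.n_persons + 1))
        cov.to_csv(out / "covariates.csv", index=False)

    imap = pd.DataFrame({
        "item": labels,
        "trait": data.items.dimension + 1,
        "direction": data.items.direction,
        "alpha": data.items.alpha,
        "delta": data.items.delta,
    })
    for k in range(data.items.C):
        imap[f"tau{k + 1}"] = data.items.tau[:, k]
    imap.to_csv(out / "itemmap.csv", index=False)

    with open(out / "condition.yaml", "w") as fh:
        yaml.safe_dump(data.condition.to_dict(), fh, sort_keys=False)
    return out
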