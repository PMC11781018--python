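"""Objective construction and acquisition functions.

Both searches are phrased as maximization.  For the ground-state global
minimum the objective is -E(S0).  For the minimum-energy conical
intersection the objective is -C with the penalty cost

    C = (E(S0) + E(S1)) / 2 + (E(S1) - E(S0))^2 / alpha,

whose first term favours low-lying geometries and whose second term drives
the two states towards degeneracy; alpha (kcal/mol) sets the trade-off.

Acquisition functions over the GP posterior (mu, sigma):

* PI  -- probability of improvement, P(f(x) >= f(x*)) = Phi((mu - f*) / sigma)
  with the incumbent f* taken from *observed* objective values;
* UCB -- mu + beta * sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .pes_models import EnergyRecord

GM = "gm"
MECI = "meci"


class IncompleteRecordError(ValueError):
    """An excited-state energy is required but missing."""


@dataclass(frozen=True)
class ObjectiveSpec:
    """Which critical structure is sought, and the degeneracy weight."""

    target: str = GM
    alpha: float = 50.0  # kcal/mol, MECI only

    def __post_init__(self):
        if self.target not in (GM, MECI):
            raise ValueError(f"target must be '{GM}' or '{MECI}'")
        if self.target == MECI and self.alpha <= 0:
            raise ValueError("alpha must be strictly positive")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition kind and its exploration weight."""

    kind: str = "pi"
    beta: float = 0.1  # UCB only

    def __post_init__(self):
        if self.kind not in ("pi", "ucb"):
            raise ValueError("acquisition kind must be 'pi' or 'ucb'")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


def cost_C(e_s0, e_s1, alpha: float):
    """Degeneracy-penalized cost (kcal/mol); the search maximizes -C."""
    if alpha <= 0:
        raise ValueError("alpha must be strictly positive")
    e_s0 = np.asarray(e_s0, dtype=float)
    e_s1 = np.asarray(e_s1, dtype=float)
    out = 0.5 * (e_s0 + e_s1) + (e_s1 - e_s0) ** 2 / alpha
    return out if out.ndim else float(out)


def objective_value(record: EnergyRecord, spec: ObjectiveSpec) -> float:
    """Observed objective (maximization convention) for one energy record."""
    if spec.target == GM:
        return -record.e_s0
    if record.e_s1 is None:
        raise IncompleteRecordError(
            "MECI objective requires both state energies"
        )
    return -cost_C(record.e_s0, record.e_s1, spec.alpha)


def objective_values(records, spec: ObjectiveSpec) -> np.ndarray:
    return np.array([objective_value(r, spec) for r in records])


def incumbent_from(values) -> float:
    """Best observed objective value f(x*)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("incumbent undefined before any evaluation")
    return float(values.max())


_SIGMA_TINY = 1e-12


def probability_of_improvement(mu, sigma, incumbent):
    """Phi((mu - f*) / sigma); at sigma = 0 the indicator of mu > f*
    (a tie counts as no improvement, so exactly re-proposed points score 0)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    safe = np.where(sigma > _SIGMA_TINY, sigma, 1.0)
    pi = ndtr((mu - incumbent) / safe)
    degenerate = (mu > incumbent).astype(float)
    out = np.where(sigma > _SIGMA_TINY, pi, degenerate)
    return out if out.ndim else float(out)


def upper_confidence_bound(mu, sigma, beta: float):
    """mu + beta * sigma (objective units)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    out = mu + beta * sigma
    return out if out.ndim else float(out)


def acquisition_values(mu, sigma, spec: AcquisitionSpec, incumbent=None):
    """Vectorized acquisition scores."""
    if spec.kind == "pi":
        return probability_of_improvement(mu, sigma, incumbent)
    return upper_confidence_bound(mu, sigma, spec.beta)


def acquisition_value_and_grad(mu, sigma, dmu, dsigma, spec: AcquisitionSpec, incumbent=None):
    """Acquisition value and gradient from posterior value/gradient pairs."""
    if spec.kind == "ucb":
        return mu + spec.beta * sigma, dmu + spec.beta * dsigma
    if sigma <= _SIGMA_TINY:
        return (1.0 if mu > incumbent else 0.0), np.zeros_like(dmu)
    z = (mu - incumbent) / sigma
    value = float(ndtr(z))
    pdf = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    grad = pdf * (dmu - z * dsigma) / sigma
    return value, grad
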