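"""The Bayesian-optimization campaign loop.

Each iteration: (1) refit the GP surrogate from scratch on all data so far,
(2) propose one candidate geometry by two-stage acquisition maximization --
2000 uniform random draws, the top 200 by acquisition value, bounded local
L-BFGS-B maximization from each, then the best collision-free optimized
point -- (3) evaluate the energy oracle (optionally through the uniform
noise wrapper), (4) apply the termination check.

Termination (patience rule): at every check iteration (multiples of 5 for
the GM search, of 50 for the MECI search) the running best is stored -- the
lowest observed E(S0) for GM; for MECI the lowest observed E(S1) among
candidates whose observed gap is below 3.0 kcal/mol.  The campaign stops
once the stored value is identical over `patience` (default 3) consecutive
checks, or unconditionally at `max_iterations`.  MECI checks at which no
candidate passes the gap filter leave the patience counter untouched; a
campaign that never stores a structure ends with status ``no_ci_found``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional

import numpy as np
from scipy.optimize import fmin_l_bfgs_b

from .acquisition import (
    GM,
    MECI,
    AcquisitionSpec,
    ObjectiveSpec,
    acquisition_value_and_grad,
    acquisition_values,
    incumbent_from,
    objective_values,
)
from .internal_coords import Geometry, SearchSpace, has_collision, sample_uniform
from .pes_models import EnergyRecord, NoisyOracle
from .regression import GaussianProcessSurrogate


class ProposalFailureError(RuntimeError):
    """Every optimized candidate collided in every allowed retry."""


class OracleError(RuntimeError):
    """Oracle evaluation failed; carries the iteration context."""


@dataclass(frozen=True)
class CampaignConfig:
    """All knobs of one campaign; the defaults are the standard protocol."""

    objective: ObjectiveSpec = field(default_factory=ObjectiveSpec)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    n_random: int = 2000
    n_select: int = 200
    collision_threshold: float = 0.5  # Angstrom
    gm_check_interval: int = 5
    ci_check_interval: int = 50
    patience: int = 3
    gap_threshold: float = 3.0  # kcal/mol
    max_iterations: int = 1000
    noise_half_width: float = 0.0  # kcal/mol; 0 disables the noise wrapper
    proposal_retry_cap: int = 10
    lbfgs_maxiter: int = 200
    af_tol: float = 1e-6
    select_mode: str = "topk"  # or "boltzmann"
    gp_epochs: int = 100
    gp_learning_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_select > self.n_random:
            raise ValueError("n_select must not exceed n_random")
        for name in ("gm_check_interval", "ci_check_interval", "patience",
                     "max_iterations", "n_random", "n_select"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.select_mode not in ("topk", "boltzmann"):
            raise ValueError("select_mode must be 'topk' or 'boltzmann'")
        if self.noise_half_width < 0:
            raise ValueError("noise_half_width must be non-negative")


@dataclass
class IterationLog:
    iteration: int
    values: np.ndarray
    af_value: float
    mu: float
    sigma: float
    e_s0: float
    e_s1: Optional[float]
    noisy: bool


@dataclass
class CheckRecord:
    iteration: int
    stored_value: Optional[float]
    stored_iteration: Optional[int]
    updated: bool


@dataclass
class CampaignState:
    """Full history and termination bookkeeping of one campaign."""

    space: SearchSpace
    config: CampaignConfig
    X_init: np.ndarray
    records_init: List[EnergyRecord]
    X_cand: List[np.ndarray] = field(default_factory=list)
    records_cand: List[EnergyRecord] = field(default_factory=list)
    logs: List[IterationLog] = field(default_factory=list)
    checks: List[CheckRecord] = field(default_factory=list)
    stored_value: Optional[float] = None
    stored_iteration: Optional[int] = None
    stale_checks: int = 0
    status: str = "running"

    @property
    def iteration(self) -> int:
        return len(self.X_cand)

    @property
    def dataset_X(self) -> np.ndarray:
        if not self.X_cand:
            return np.asarray(self.X_init, dtype=float)
        return np.vstack([self.X_init, np.vstack(self.X_cand)])

    @property
    def dataset_records(self) -> List[EnergyRecord]:
        return list(self.records_init) + list(self.records_cand)

    def candidate_e_s0(self) -> np.ndarray:
        return np.array([r.e_s0 for r in self.records_cand])

    def final_geometry(self):
        """Reported result: (values, record, iteration) or None.

        GM: the candidate with the lowest observed E(S0).  MECI: the last
        stored check structure (lowest observed E(S1) under the gap filter).
        """
        if self.config.objective.target == GM:
            if not self.records_cand:
                return None
            i = int(np.argmin(self.candidate_e_s0()))
            return self.X_cand[i], self.records_cand[i], i + 1
        if self.stored_iteration is None:
            return None
        i = self.stored_iteration - 1
        return self.X_cand[i], self.records_cand[i], self.stored_iteration


@dataclass(frozen=True)
class ProposalResult:
    values: np.ndarray
    af_value: float
    mu: float
    sigma: float
    attempts: int


def _select_starts(af: np.ndarray, k: int, mode: str, rng) -> np.ndarray:
    if mode == "topk":
        order = np.argsort(-af, kind="stable")
        return order[:k]
    # Boltzmann-weighted sampling without replacement, temperature = score std
    scale = af.std()
    if scale < 1e-12:
        return rng.choice(af.size, size=k, replace=False)
    logits = (af - af.max()) / scale
    weights = np.exp(logits)
    weights /= weights.sum()
    return rng.choice(af.size, size=k, replace=False, p=weights)


def propose_candidate(
    surrogate: GaussianProcessSurrogate,
    space: SearchSpace,
    config: CampaignConfig,
    incumbent: Optional[float],
    rng,
) -> ProposalResult:
    """Two-stage acquisition maximization returning one collision-free
    candidate.  Deterministic given the generator state and the surrogate."""
    spec = config.acquisition
    bounds = space.bounds

    def neg_af_and_grad(x):
        mu, sigma, dmu, dsigma = surrogate.predict_gradient(x)
        value, grad = acquisition_value_and_grad(
            mu, sigma, dmu, dsigma, spec, incumbent
        )
        return -value, -grad

    for attempt in range(1, config.proposal_retry_cap + 1):
        Xr = sample_uniform(space, config.n_random, rng)
        mu, sigma = surrogate.predict(Xr, return_std=True)
        af = np.asarray(acquisition_values(mu, sigma, spec, incumbent))
        starts = _select_starts(af, config.n_select, config.select_mode, rng)

        factr = config.af_tol / np.finfo(float).eps
        optimized = []
        for idx in starts:
            x_opt, f_opt, _ = fmin_l_bfgs_b(
                neg_af_and_grad,
                Xr[idx],
                bounds=bounds,
                maxiter=config.lbfgs_maxiter,
                factr=factr,
            )
            if np.isfinite(f_opt):
                optimized.append((float(-f_opt), space.clip(x_opt)))
        optimized.sort(key=lambda item: -item[0])
        for af_value, x in optimized:
            geom = Geometry(x, space)
            if not has_collision(geom, config.collision_threshold):
                mu_x, sigma_x = surrogate.predict(x[None, :], return_std=True)
                return ProposalResult(
                    values=x,
                    af_value=af_value,
                    mu=float(mu_x[0]),
                    sigma=float(sigma_x[0]),
                    attempts=attempt,
                )
    raise ProposalFailureError(
        f"all optimized candidates collided in {config.proposal_retry_cap} attempts"
    )


def _apply_check(state: CampaignState, current: Optional[float], iteration: int) -> bool:
    """Shared patience bookkeeping; returns True when the campaign should stop.

    ``current`` is the running best at this check (None while the MECI gap
    filter has matched nothing, which leaves the counter untouched).
    """
    cfg = state.config
    if current is None:
        state.checks.append(
            CheckRecord(iteration, state.stored_value, state.stored_iteration, False)
        )
        return False
    updated = state.stored_value is None or current < state.stored_value
    if updated:
        state.stored_value = current
        state.stale_checks = 1
    else:
        state.stale_checks += 1
    state.checks.append(
        CheckRecord(iteration, state.stored_value, state.stored_iteration, updated)
    )
    return state.stale_checks >= cfg.patience


def check_termination_gm(state: CampaignState, config: CampaignConfig) -> bool:
    """Multiple-of-`gm_check_interval` patience rule on min observed E(S0)."""
    i = state.iteration
    stop = False
    if i % config.gm_check_interval == 0 and state.records_cand:
        current = float(np.min(state.candidate_e_s0()))
        if state.stored_value is None or current < state.stored_value:
            state.stored_iteration = int(np.argmin(state.candidate_e_s0())) + 1
        stop = _apply_check(state, current, i)
        if stop:
            state.status = "converged"
    if not stop and i >= config.max_iterations:
        state.status = "max_iterations"
        stop = True
    return stop


def check_termination_ci(state: CampaignState, config: CampaignConfig) -> bool:
    """Multiple-of-`ci_check_interval` patience rule on the lowest observed
    E(S1) among gap-filtered candidates (strict gap < gap_threshold)."""
    i = state.iteration
    stop = False
    if i % config.ci_check_interval == 0:
        best = None
        best_iter = None
        for j, rec in enumerate(state.records_cand):
            gap = rec.gap
            if gap is None or not gap < config.gap_threshold:
                continue
            if best is None or rec.e_s1 < best:  # strict: ties keep earliest
                best = float(rec.e_s1)
                best_iter = j + 1
        if best is not None and (
            state.stored_value is None or best < state.stored_value
        ):
            state.stored_iteration = best_iter
        stop = _apply_check(state, best, i)
        if stop:
            state.status = "converged"
    if not stop and i >= config.max_iterations:
        state.status = "max_iterations" if state.stored_value is not None else "no_ci_found"
        stop = True
    return stop


def check_termination(state: CampaignState, config: CampaignConfig) -> bool:
    if config.objective.target == GM:
        return check_termination_gm(state, config)
    return check_termination_ci(state, config)


def run_campaign(
    config: CampaignConfig,
    space: SearchSpace,
    oracle: Callable,
    initial_X,
    initial_records,
) -> CampaignState:
    """Execute fit -> propose -> evaluate -> check until termination.

    ``oracle`` maps a coordinate vector to an :class:`EnergyRecord`; when
    ``config.noise_half_width > 0`` it is wrapped in the seeded uniform-noise
    emulator.  The initial dataset must be non-empty and, for the MECI
    target, must carry excited-state energies.
    """
    initial_X = np.atleast_2d(np.asarray(initial_X, dtype=float))
    initial_records = list(initial_records)
    if initial_X.shape[0] == 0:
        raise ValueError("initial dataset must be non-empty")
    if initial_X.shape[0] != len(initial_records):
        raise ValueError("initial geometries and records disagree in length")
    if config.objective.target == MECI:
        for rec in initial_records:
            if rec.e_s1 is None:
                raise ValueError("MECI search requires two-state records")

    ss = np.random.SeedSequence(config.seed)
    proposal_seed, noise_seed = ss.spawn(2)
    rng_proposal = np.random.default_rng(proposal_seed)
    if config.noise_half_width > 0:
        oracle = NoisyOracle(oracle, config.noise_half_width, noise_seed)

    state = CampaignState(
        space=space,
        config=config,
        X_init=initial_X,
        records_init=initial_records,
    )
    surrogate = GaussianProcessSurrogate(
        epochs=config.gp_epochs, learning_rate=config.gp_learning_rate
    )

    while True:
        i = state.iteration + 1
        y = objective_values(state.dataset_records, config.objective)
        surrogate.fit(state.dataset_X, y)
        incumbent = incumbent_from(y)
        proposal = propose_candidate(surrogate, space, config, incumbent, rng_proposal)
        try:
            record = oracle(proposal.values)
        except Exception as exc:  # attach iteration context
            raise OracleError(f"oracle failed at iteration {i}") from exc
        record = replace(record, geometry_ref=f"iter{i:04d}")
        state.X_cand.append(proposal.values)
        state.records_cand.append(record)
        state.logs.append(
            IterationLog(
                iteration=i,
                values=proposal.values,
                af_value=proposal.af_value,
                mu=proposal.mu,
                sigma=proposal.sigma,
                e_s0=record.e_s0,
                e_s1=record.e_s1,
                noisy=record.noisy,
            )
        )
        if check_termination(state, config):
            break
    return state
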