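import numpy as np
import pytest

from bogeom.acquisition import AcquisitionSpec, ObjectiveSpec
from bogeom.bo_loop import (
    CampaignConfig,
    CampaignState,
    ProposalFailureError,
    check_termination,
    propose_candidate,
    run_campaign,
)
from bogeom.internal_coords import (
    ABSTRACT,
    DISTANCE,
    SearchSpace,
    ZMatrixAtom,
)
from bogeom.pes_models import EnergyRecord


def _play_history(records, config, space):
    """Feed a constructed candidate history through the termination check,
    one iteration at a time; returns (stop_iteration, state)."""
    state = CampaignState(
        space=space,
        config=config,
        X_init=np.zeros((1, space.ndim)),
        records_init=[EnergyRecord(0.0, 0.0)],
    )
    for rec in records:
        state.X_cand.append(np.zeros(space.ndim))
        state.records_cand.append(rec)
        if check_termination(state, config):
            return state.iteration, state
    return None, state


def _gm_config(**kwargs):
    return CampaignConfig(objective=ObjectiveSpec("gm"), **kwargs)


def _ci_config(**kwargs):
    return CampaignConfig(objective=ObjectiveSpec("meci", 50.0), **kwargs)


def _gm_history(best_iterations, n, base=10.0):
    """E(S0) history: value drops by 1 at each iteration in best_iterations."""
    records = []
    level = base
    for i in range(1, n + 1):
        if i in best_iterations:
            level -= 1.0
        records.append(EnergyRecord(level if i in best_iterations else base + 5))
    return records


class TestGmTermination:
    def test_best_before_first_check_stops_after_three_stale_checks(self, space2d):
        # best at iteration 4, never improved -> checks 5, 10, 15 unchanged
        records = _gm_history({4}, 40)
        stop, state = _play_history(records, _gm_config(), space2d)
        assert stop == 15
        assert state.status == "converged"
        assert [c.iteration for c in state.checks] == [5, 10, 15]

    def test_improvement_resets_patience(self, space2d):
        # improvement at iteration 12 resets the counter at the check of 15
        records = _gm_history({4, 12}, 40)
        stop, state = _play_history(records, _gm_config(), space2d)
        assert stop == 25
        check15 = [c for c in state.checks if c.iteration == 15][0]
        assert check15.updated

    def test_equal_value_does_not_reset(self, space2d):
        # a tie with the stored best is not an update
        records = [EnergyRecord(5.0)] + [EnergyRecord(5.0)] * 39
        stop, _ = _play_history(records, _gm_config(), space2d)
        assert stop == 15

    def test_forced_stop_at_iteration_cap(self, space2d):
        # strictly improving forever: only the cap stops the campaign
        records = [EnergyRecord(-float(i)) for i in range(1, 2000)]
        stop, state = _play_history(records, _gm_config(), space2d)
        assert stop == 1000
        assert state.status == "max_iterations"

    def test_reported_minimum_is_monotone_in_iteration(self, space2d, rng):
        records = [EnergyRecord(e) for e in rng.normal(10, 5, 60)]
        running = np.minimum.accumulate([r.e_s0 for r in records])
        state = CampaignState(
            space=space2d, config=_gm_config(),
            X_init=np.zeros((1, 2)), records_init=[EnergyRecord(0.0)],
        )
        for i, rec in enumerate(records):
            state.X_cand.append(np.zeros(2))
            state.records_cand.append(rec)
            assert state.candidate_e_s0().min() == running[i]


class TestCiTermination:
    @staticmethod
    def _ci_records(n, qualifying):
        """History where iteration i has (e_s0, e_s1); ``qualifying`` maps
        iteration -> (e_s1, gap)."""
        records = []
        for i in range(1, n + 1):
            if i in qualifying:
                e1, gap = qualifying[i]
                records.append(EnergyRecord(e1 - gap, e1))
            else:
                records.append(EnergyRecord(0.0, 50.0))  # gap 50: filtered out
        return records

    def test_single_qualifier_stops_after_three_identical_checks(self, space2d):
        # qualifying structure at iteration 60, never bettered:
        # stored first at check 100, unchanged at 150 and 200 -> stop at 200
        records = self._ci_records(300, {60: (20.0, 1.0)})
        stop, state = _play_history(records, _ci_config(), space2d)
        assert stop == 200
        assert state.status == "converged"
        assert state.stored_iteration == 60

    def test_never_qualifying_runs_to_cap_with_no_ci_status(self, space2d):
        records = self._ci_records(1200, {})
        stop, state = _play_history(records, _ci_config(), space2d)
        assert stop == 1000
        assert state.status == "no_ci_found"
        assert state.final_geometry() is None

    def test_gap_filter_is_strict(self, space2d):
        # gap exactly at the threshold is excluded
        records = self._ci_records(1200, {10: (20.0, 3.0)})
        stop, state = _play_history(records, _ci_config(), space2d)
        assert state.status == "no_ci_found"

    def test_tie_on_e_s1_keeps_earlier_iteration(self, space2d):
        records = self._ci_records(300, {30: (20.0, 1.0), 70: (20.0, 0.5)})
        stop, state = _play_history(records, _ci_config(), space2d)
        assert state.stored_iteration == 30

    def test_later_improvement_resets_patience(self, space2d):
        # stored at 50; strictly better structure at 120 resets at check 150
        records = self._ci_records(400, {40: (20.0, 1.0), 120: (15.0, 1.0)})
        stop, state = _play_history(records, _ci_config(), space2d)
        assert stop == 250
        assert state.stored_iteration == 120
        assert state.final_geometry()[2] == 120


class _QuadraticPosterior:
    """Duck-typed surrogate with a known acquisition landscape: mean is a
    mixture of two Gaussian bumps, variance constant."""

    def __init__(self, centers, heights, width=0.15, sigma=0.05):
        self.centers = np.atleast_2d(centers)
        self.heights = np.asarray(heights, dtype=float)
        self.width = width
        self.sigma = sigma

    def _mu(self, X):
        X = np.atleast_2d(X)
        d2 = ((X[:, None, :] - self.centers[None]) ** 2).sum(-1)
        return (self.heights * np.exp(-0.5 * d2 / self.width**2)).sum(axis=1)

    def predict(self, X, return_std=False):
        mu = self._mu(X)
        if not return_std:
            return mu
        return mu, np.full(mu.shape, self.sigma)

    def predict_gradient(self, x):
        x = np.asarray(x, dtype=float)
        diff = self.centers - x
        d2 = (diff**2).sum(-1)
        w = self.heights * np.exp(-0.5 * d2 / self.width**2)
        mu = w.sum()
        dmu = (w[:, None] * diff).sum(axis=0) / self.width**2
        return float(mu), self.sigma, dmu, np.zeros_like(x)


class TestProposeCandidate:
    def test_finds_interior_acquisition_maximum(self):
        space = SearchSpace(("x",), (ABSTRACT,), [0.0], [1.0])
        surrogate = _QuadraticPosterior([[0.37]], [1.0])
        config = CampaignConfig(
            objective=ObjectiveSpec("gm"), acquisition=AcquisitionSpec("ucb", 0.0)
        )
        rng = np.random.default_rng(0)
        proposal = propose_candidate(surrogate, space, config, None, rng)
        # dense-grid oracle for the same acquisition landscape
        grid = np.linspace(0, 1, 200001)[:, None]
        best = grid[np.argmax(surrogate.predict(grid))][0]
        assert proposal.values[0] == pytest.approx(best, abs=1e-3)

    def test_determinism_under_same_generator_state(self):
        space = SearchSpace(("x", "y"), (ABSTRACT, ABSTRACT), [0.0, 0.0], [1.0, 1.0])
        surrogate = _QuadraticPosterior([[0.3, 0.7], [0.8, 0.2]], [1.0, 0.9])
        config = CampaignConfig(objective=ObjectiveSpec("gm"))
        a = propose_candidate(surrogate, space, config, 0.5, np.random.default_rng(5))
        b = propose_candidate(surrogate, space, config, 0.5, np.random.default_rng(5))
        assert np.array_equal(a.values, b.values)
        assert a.af_value == b.af_value

    @staticmethod
    def _diatomic_space(lower=0.2):
        return SearchSpace(
            ("r1",), (DISTANCE,), [lower], [2.0],
            topology=(
                ZMatrixAtom("H"),
                ZMatrixAtom("H", distance_ref=0, distance="r1"),
            ),
        )

    def test_colliding_maximum_yields_second_best(self):
        # global acquisition maximum at r = 0.35 (a collision); a lower peak
        # at r = 1.2 is the best collision-free candidate
        space = self._diatomic_space()
        # narrow peaks so the top-k start pool spans both basins
        surrogate = _QuadraticPosterior([[0.35], [1.2]], [1.0, 0.6], width=0.05)
        config = CampaignConfig(
            objective=ObjectiveSpec("gm"), acquisition=AcquisitionSpec("ucb", 0.0)
        )
        proposal = propose_candidate(
            surrogate, space, config, None, np.random.default_rng(1)
        )
        assert proposal.values[0] == pytest.approx(1.2, abs=1e-3)

    def test_all_colliding_raises_after_retry_cap(self):
        # one very broad basin pulls every start into the collision zone
        space = self._diatomic_space()
        surrogate = _QuadraticPosterior([[0.25]], [1.0], width=3.0)
        config = CampaignConfig(
            objective=ObjectiveSpec("gm"),
            acquisition=AcquisitionSpec("ucb", 0.0),
            proposal_retry_cap=2,
            n_random=50,
            n_select=50,
        )
        with pytest.raises(ProposalFailureError):
            propose_candidate(surrogate, space, config, None, np.random.default_rng(2))


class TestRunCampaign:
    def test_single_iteration_budget(self, model2d, space2d, rng):
        X0 = rng.uniform(space2d.lower, space2d.upper, (5, 2))
        records = [model2d(x) for x in X0]
        config = CampaignConfig(objective=ObjectiveSpec("gm"), max_iterations=1, seed=3)
        state = run_campaign(config, space2d, model2d, X0, records)
        assert state.iteration == 1
        assert len(state.records_cand) == 1
        assert state.status == "max_iterations"
        assert state.final_geometry() is not None

    def test_dataset_grows_by_one_per_iteration(self, model2d, space2d, rng):
        X0 = rng.uniform(space2d.lower, space2d.upper, (6, 2))
        records = [model2d(x) for x in X0]
        config = CampaignConfig(objective=ObjectiveSpec("gm"), max_iterations=4, seed=9)
        state = run_campaign(config, space2d, model2d, X0, records)
        assert len(state.dataset_records) == 6 + state.iteration
        assert state.dataset_X.shape == (6 + state.iteration, 2)

    def test_full_determinism_of_logged_history(self, model2d, space2d, rng):
        X0 = rng.uniform(space2d.lower, space2d.upper, (6, 2))
        records = [model2d(x) for x in X0]
        config = CampaignConfig(
            objective=ObjectiveSpec("gm"), max_iterations=3,
            noise_half_width=2.0, seed=17,
        )
        a = run_campaign(config, space2d, model2d, X0, list(records))
        b = run_campaign(config, space2d, model2d, X0, list(records))
        for la, lb in zip(a.logs, b.logs):
            assert np.array_equal(la.values, lb.values)
            assert la.e_s0 == lb.e_s0 and la.e_s1 == lb.e_s1
            assert la.af_value == lb.af_value

    def test_meci_requires_two_state_records(self, model2d, space2d):
        X0 = np.zeros((2, 2))
        records = [EnergyRecord(1.0), EnergyRecord(2.0)]
        config = CampaignConfig(objective=ObjectiveSpec("meci", 50.0))
        with pytest.raises(ValueError):
            run_campaign(config, space2d, model2d, X0, records)

    def test_empty_initial_dataset_rejected(self, model2d, space2d):
        with pytest.raises(ValueError):
            run_campaign(
                CampaignConfig(), space2d, model2d, np.zeros((0, 2)), []
            )


def test_config_validation():
    with pytest.raises(ValueError):
        CampaignConfig(n_random=100, n_select=200)
    with pytest.raises(ValueError):
        CampaignConfig(patience=0)
    with pytest.raises(ValueError):
        CampaignConfig(noise_half_width=-1.0)
    with pytest.raises(ValueError):
        CampaignConfig(select_mode="magic")
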