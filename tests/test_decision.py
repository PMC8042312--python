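import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeforage import (
    DecisionParams,
    PatchClass,
    RaceState,
    check_threshold,
    drift_rates,
    gazing_function,
    relative_value,
    run_race,
    step_race,
)

from conftest import make_patch, static_landscape


class TestGazingFunction:
    def test_other_patch_is_undiscounted(self):
        assert gazing_function(2, 1, 5.0, 0.5, 0.18) == 1.0

    def test_zero_time_on_patch(self):
        assert gazing_function(1, 1, 0.0, 0.5, 0.18) == 1.0

    def test_exponential_decay_value(self):
        # exp(-phi * V * t) with phi=0.18, V=1, t=1
        assert gazing_function(1, 1, 1.0, 1.0, 0.18) == pytest.approx(0.835270, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            gazing_function(1, 1, -0.1, 0.5, 0.18)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        t=st.floats(0, 1e3),
        v=st.floats(0, 1),
        phi=st.floats(1e-6, 10),
        same=st.booleans(),
    )
    def test_always_in_unit_interval(self, t, v, phi, same):
        psi = gazing_function(1, 1 if same else 2, t, v, phi)
        # exp(-x) may underflow to exactly 0 for extreme exponents
        assert 0.0 <= psi <= 1.0
        if phi * v * t < 100:
            assert psi > 0.0


class TestRelativeValue:
    def test_current_patch_gives_eta(self):
        frame = [make_patch(1, 100, 100, value=0.5)]
        assert relative_value(1, 1, frame, eta=5, kappa=15) == pytest.approx(5.0)

    def test_worked_example(self):
        # eta=5, kappa=15, V_p=0.2, V_p*=0.5, normalized distance 0.1
        frame = [
            make_patch(1, 0, 0, value=0.5),
            make_patch(2, 100, 0, value=0.2),
        ]
        out = relative_value(2, 1, frame, eta=5, kappa=15, diag=1000.0)
        assert out == pytest.approx(5 * 0.4 * np.exp(-1.5), abs=1e-6)
        assert out == pytest.approx(0.446260, abs=1e-6)

    def test_large_kappa_limit(self):
        frame = [make_patch(1, 0, 0, value=0.5), make_patch(2, 100, 0, value=0.2)]
        assert relative_value(2, 1, frame, eta=5, kappa=1e6, diag=1000.0) == pytest.approx(0.0)

    def test_zero_current_value_rejected(self):
        frame = [make_patch(1, 0, 0, value=0.0), make_patch(2, 100, 0, value=0.2)]
        with pytest.raises(ValueError, match="nonpositive"):
            relative_value(2, 1, frame, eta=5, kappa=15, diag=1000.0)


class TestDriftRates:
    def test_current_patch_at_entry_equals_eta(self, params):
        frame = [make_patch(1, 100, 100, value=0.5), make_patch(2, 600, 100, value=0.2)]
        state = RaceState.fresh([1, 2], p_star=1)
        drifts = drift_rates(state, frame, params, diag=1468.6)
        assert drifts[0] == pytest.approx(params.eta)

    def test_colocated_equal_value_patches_symmetric(self, params):
        frame = [make_patch(1, 100, 100, value=0.5), make_patch(2, 100, 100, value=0.5)]
        state = RaceState.fresh([1, 2], p_star=1)
        drifts = drift_rates(state, frame, params, diag=1468.6)
        assert drifts[0] == pytest.approx(drifts[1])

    def test_composition_of_gazing_and_relative_value(self, params):
        frame = [make_patch(1, 0, 0, value=0.5), make_patch(2, 146.86, 0, value=0.2)]
        state = RaceState.fresh([1, 2], p_star=1)
        drifts = drift_rates(state, frame, params, diag=1468.6)
        assert drifts[1] == pytest.approx(0.446260, abs=1e-5)

    def test_current_drift_non_increasing_in_time_on_patch(self, params):
        frame = [make_patch(1, 100, 100, value=0.5), make_patch(2, 600, 100, value=0.2)]
        prev = np.inf
        for t in [0.0, 1.0, 5.0, 20.0]:
            state = RaceState.fresh([1, 2], p_star=1, t_on_patch=t)
            cur = drift_rates(state, frame, params, diag=1468.6)[0]
            assert cur <= prev
            prev = cur


class TestStepRace:
    def test_noise_free_euler(self):
        params = DecisionParams(c=0.0, dt=0.5)
        state = RaceState.fresh([1], p_star=1)
        out = step_race(state, np.array([2.0]), params, np.random.default_rng(0))
        assert out.q[0] == pytest.approx(1.0)
        assert out.t_on_patch == pytest.approx(0.5)

    def test_increment_moments_match_gaussian(self, rng):
        # c=1, I=0: increments are N(0, dt)
        params = DecisionParams(c=1.0, dt=0.01)
        n = 10**5
        state = RaceState.fresh(list(range(n)), p_star=0)
        out = step_race(state, np.zeros(n), params, rng)
        inc = out.q
        se_mean = np.sqrt(params.dt / n)
        assert abs(inc.mean()) < 4 * se_mean
        se_var = params.dt * np.sqrt(2.0 / (n - 1))
        assert abs(inc.var(ddof=1) - params.dt) < 4 * se_var

    def test_shape_mismatch_rejected(self, params, rng):
        state = RaceState.fresh([1, 2], p_star=1)
        with pytest.raises(ValueError):
            step_race(state, np.array([1.0]), params, rng)


class TestCheckThreshold:
    def test_below_threshold_none(self):
        state = RaceState(q=np.array([0.3, 0.5]), p_star=1, t_on_patch=0, patch_ids=[1, 2])
        assert check_threshold(state, 1.7) is None

    def test_single_crosser_wins(self):
        state = RaceState(q=np.array([1.8, 0.2]), p_star=1, t_on_patch=0, patch_ids=[1, 2])
        assert check_threshold(state, 1.7) == 1

    def test_max_q_rule_and_tie_break(self):
        state = RaceState(q=np.array([1.8, 1.9]), p_star=1, t_on_patch=0, patch_ids=[1, 2])
        assert check_threshold(state, 1.7) == 2
        tie = RaceState(q=np.array([1.8, 1.8]), p_star=5, t_on_patch=0, patch_ids=[5, 3])
        assert check_threshold(tie, 1.7) == 3


class TestRunRace:
    def test_noise_free_closed_form(self):
        # constant drifts (2, 1), a=1: winner is the faster racer at t = a/I = 0.5 s
        frame = [
            make_patch(1, 100, 100, value=0.5),
            make_patch(2, 100, 100, value=0.25),
        ]
        scene = static_landscape(frame)
        params = DecisionParams(phi=1e-12, eta=2.0, a=1.0, c=0.0)
        state = RaceState.fresh([1, 2], p_star=1)
        out = run_race(state, scene, params, np.random.default_rng(0))
        assert out.winner == 1
        assert abs(out.decision_time - 0.5) <= params.dt + 1e-12

    def test_traces_cover_race(self):
        frame = [make_patch(1, 100, 100, value=0.5)]
        scene = static_landscape(frame)
        params = DecisionParams(phi=1e-12, a=1.0, c=0.0)
        out = run_race(RaceState.fresh([1], 1), scene, params, np.random.default_rng(0))
        assert out.trace_q.shape == (len(out.trace_t), 1)
        assert out.trace_t[-1] == pytest.approx(out.decision_time)
        assert np.all(np.diff(out.trace_q[:, 0]) > 0)

    def test_nonzero_initial_evidence_rejected(self, two_patch_scene, params, rng):
        state = RaceState(q=np.array([0.5, 0.0]), p_star=1, t_on_patch=0, patch_ids=[1, 2])
        with pytest.raises(ValueError, match="q = 0"):
            run_race(state, two_patch_scene, params, rng)

    def test_timeout_on_degenerate_parameters(self):
        frame = [make_patch(1, 100, 100, value=0.5)]
        scene = static_landscape(frame)
        params = DecisionParams(phi=1e-12, eta=1e-6, a=1.7, c=0.0, max_race_s=2.0)
        with pytest.raises(TimeoutError):
            run_race(RaceState.fresh([1], 1), scene, params, np.random.default_rng(0))

    def test_exchangeable_racers_win_equally_often(self):
        frame = [
            make_patch(1, 100, 100, value=0.5),
            make_patch(2, 100, 100, value=0.5),
        ]
        scene = static_landscape(frame)
        params = DecisionParams(phi=1e-12)
        rng = np.random.default_rng(7)
        n = 2000
        wins = sum(
            run_race(RaceState.fresh([1, 2], 1), scene, params, rng,
                     record_traces=False).winner == 1
            for _ in range(n)
        )
        se = np.sqrt(0.25 / n)
        assert abs(wins / n - 0.5) < 4 * se

    def test_id_relabeling_equivariance(self):
        """Evidence traces do not depend on patch id labels, only on geometry."""
        params = DecisionParams(c=0.0, phi=1e-12)
        outs = []
        for ids in ([1, 2], [10, 20]):
            frame = [
                make_patch(ids[0], 100, 100, value=0.5),
                make_patch(ids[1], 400, 100, value=0.2),
            ]
            scene = static_landscape(frame)
            outs.append(
                run_race(RaceState.fresh(ids, ids[0]), scene, params,
                         np.random.default_rng(0))
            )
        assert np.allclose(outs[0].trace_q, outs[1].trace_q)
        assert outs[1].winner == 10 * outs[0].winner


class TestRaceStateSync:
    def test_disappearing_patch_dropped_new_patch_joins_zero(self):
        state = RaceState(q=np.array([0.4, 0.9]), p_star=1, t_on_patch=1.0, patch_ids=[1, 2])
        synced = state.sync_patches([1, 3])
        assert synced.patch_ids == [1, 3]
        assert synced.q[0] == 0.4 and synced.q[1] == 0.0
        assert synced.t_on_patch == 1.0


class TestDecisionParams:
    @pytest.mark.parametrize("bad", [{"phi": 0}, {"eta": -1}, {"a": 0}, {"c": -0.1}, {"dt": 0}])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            DecisionParams(**bad)

    def test_grid_search_defaults(self):
        p = DecisionParams()
        assert (p.phi, p.eta, p.kappa, p.a, p.c) == (0.18, 5.0, 15.0, 1.7, 1.0)
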