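import numpy as np
import pytest

from cnvbeast import CutoffParams, backward_eliminate, call_track, cleanup, consolidate, init_saturated, segment_level
from cnvbeast.engine import JumpModel
from cnvbeast.simulate import PlantedCNV, simulate_track

from conftest import make_track


def refit(model):
    """From-scratch refit of the same active jump set (the oracle)."""
    return JumpModel(model.y, model.params, jumps=model.active_jumps(),
                     truncate=model.truncate, objective=model.objective)


def assert_state_equal(a, b):
    assert a.active_jumps() == b.active_jumps()
    for k in a.active_jumps():
        assert a.gap[k] == b.gap[k]
        assert a.level_r[k] == pytest.approx(b.level_r[k], abs=1e-12)
        assert a.beta[k] == pytest.approx(b.beta[k], abs=1e-12)
        assert a.delta[k] == pytest.approx(b.delta[k], rel=1e-9, abs=1e-9)


class TestSaturated:
    def test_betas_are_successive_differences(self, params_s1):
        m = init_saturated(make_track([0.1, 0.5, 0.2]), params_s1)
        assert [m.beta[k] for k in (0, 1, 2)] == pytest.approx([0.1, 0.4, -0.3])
        np.testing.assert_allclose(m.fitted_values(), [0.1, 0.5, 0.2])

    def test_constant_track(self, params_s1):
        m = init_saturated(make_track([0.7] * 10), params_s1)
        assert m.beta[0] == pytest.approx(0.7)
        assert all(m.beta[k] == pytest.approx(0.0) for k in range(1, 10))

    def test_exact_fit_on_random_data(self, params_s1):
        y = np.random.default_rng(0).standard_t(5, 200) * 0.27
        m = init_saturated(make_track(y), params_s1)
        np.testing.assert_allclose(m.fitted_values(), y, atol=1e-14)
        assert all(m.gap[k] == 1 for k in range(200))


class TestSegmentLevel:
    def test_odd_and_even(self, params_s1):
        tr = make_track([0.1, 0.2, 0.9, 0.3])
        assert segment_level(tr, 1, 3) == pytest.approx(0.2)
        assert segment_level(tr, 1, 2) == pytest.approx(0.15)

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=1001)
        tr = make_track(y)
        expect = np.sort(y)[500]  # middle order statistic
        assert segment_level(tr, 1, 1001) == pytest.approx(expect)

    def test_empty_range_error(self, params_s1):
        with pytest.raises(ValueError):
            segment_level(make_track([0.0, 1.0]), 2, 1)


class TestRemoveJump:
    def test_merge_matches_full_refit(self, params_s1):
        y = np.concatenate([np.full(10, 0.4), np.full(10, 0.9), np.full(10, 0.1)])
        y += np.random.default_rng(1).normal(0, 0.05, 30)
        m = JumpModel(y, params_s1, jumps=[0, 10, 20])
        before_delta_20 = m.delta[20]
        m.remove_jump(10)
        assert_state_equal(m, refit(m))
        assert m.delta[20] != before_delta_20  # neighbor was refreshed

    def test_removing_zero_beta_jump_changes_nothing_else(self, params_s1):
        y = np.zeros(30)
        y[10:] = 0.5
        m = JumpModel(y, params_s1, jumps=[10, 20])
        assert m.beta[20] == pytest.approx(0.0)
        m.remove_jump(20)
        assert m.beta[10] == pytest.approx(0.5)
        np.testing.assert_allclose(m.fitted_values(), y, atol=1e-14)

    def test_removing_only_jump_restores_flat_baseline(self, params_s1):
        y = np.zeros(30)
        y[10:] = 0.5
        m = JumpModel(y, params_s1, jumps=[10])
        m.remove_jump(10)
        assert m.active_jumps() == []
        np.testing.assert_allclose(m.fitted_values(), 0.0, atol=1e-14)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_removal_sequences_match_refit(self, seed, params_s1):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        y = rng.standard_t(5, n) * 0.275
        m = JumpModel(y, params_s1)
        order = rng.permutation(n)
        for k in order[: int(rng.integers(1, n))]:
            m.remove_jump(int(k))
        assert_state_equal(m, refit(m))

    def test_inactive_jump_error(self, params_s1):
        m = JumpModel(np.zeros(10), params_s1, jumps=[3])
        with pytest.raises(ValueError):
            m.remove_jump(5)


class TestSelectRemoval:
    def test_rising_pair_keeps_outer_left_jump(self, params_s1):
        # two +0.4 steps up from baseline: candidate is the first jump
        # (leftmost tie-break) but the second is returned for removal
        y = np.zeros(30)
        y[8:12] = 0.4
        y[12:] = 0.8
        m = JumpModel(y, params_s1, jumps=[8, 12])
        assert m.select_removal() == 12

    def test_falling_pair_keeps_outer_right_jump(self, params_s1):
        # descent 0.8 -> 0.45 -> 0.15 on the positive side: candidate is
        # the second (smaller-score) jump, but the first is returned
        y = np.zeros(60)
        y[10:28] = 0.8
        y[28:33] = 0.45
        y[33:] = 0.15
        m = JumpModel(y, params_s1, jumps=[10, 28, 33])
        assert m.select_removal() == 28

    def test_isolated_jump_returns_itself(self, params_s1):
        y = np.zeros(30)
        y[14:18] = 0.4
        m = JumpModel(y, params_s1, jumps=[13, 17])
        # candidate 13 has a neighbor of opposite sign: no override
        assert m.select_removal() in (13, 17)
        k = m.select_removal()
        assert m.beta[k] != 0

    def test_noise_level_shoulder_does_not_trigger_override(self, params_s1):
        # middle level below mu_min: override must not fire
        y = np.zeros(30)
        y[8:12] = 0.1
        y[12:] = 0.8
        m = JumpModel(y, params_s1, jumps=[8, 12])
        assert m.select_removal() == 8

    def test_none_when_all_satisfied(self, params_s1):
        y = np.zeros(30)
        y[10:20] = 0.6
        m = JumpModel(y, params_s1, jumps=[10, 20])
        assert m.select_removal() is None


class TestBackwardEliminate:
    def test_noiseless_cnv(self, noiseless_cnv_track, params_s1):
        m = backward_eliminate(noiseless_cnv_track, params_s1)
        assert m.active_jumps() == [10, 20]
        assert m.beta[10] == pytest.approx(0.6)
        assert m.beta[20] == pytest.approx(-0.6)
        assert m.gap[10] == m.gap[20] == 10
        assert all(m.delta[k] >= 0 for k in m.active_jumps())

    def test_pure_zero_track(self, params_s1):
        m = backward_eliminate(make_track(np.zeros(30)), params_s1)
        assert m.active_jumps() == []

    def test_short_cnv_below_m_min_is_erased(self, params_s1):
        y = np.zeros(30)
        y[13:17] = 0.6  # only 4 probes < m_min = 6
        m = backward_eliminate(make_track(y), params_s1)
        assert m.active_jumps() == []

    def test_termination_criterion_holds(self, params_s1):
        track, _ = simulate_track(800, cnvs=[PlantedCNV(300, 60, 0.6)], seed=3)
        m = backward_eliminate(track, params_s1)
        for k in m.active_jumps():
            assert m.delta[k] >= 0
            assert m.gap[k] >= params_s1.m_min


class TestCleanup:
    def test_sub_floor_plateau_zeroed_between_cnvs(self, params_s1):
        y = np.zeros(70)
        y[10:30] = 0.6
        y[30:40] = 0.1  # below mu_min: must be flattened to 0
        y[40:60] = 0.6
        tr = make_track(y)
        m = backward_eliminate(tr, params_s1)
        c = cleanup(tr, m, params_s1)
        levels = {round(lev, 6) for _, _, lev in c.segments()}
        assert levels == {0.0, 0.6}

    def test_identity_when_levels_already_clean(self, noiseless_cnv_track, params_s1):
        m = backward_eliminate(noiseless_cnv_track, params_s1)
        c = cleanup(noiseless_cnv_track, m, params_s1)
        assert c.active_jumps() == m.active_jumps()

    def test_faint_long_cnv_removed_entirely(self):
        p = CutoffParams(score_min=0.5)
        y = np.zeros(100)
        y[25:75] = 0.2  # 50 probes > m_max but below mu_min
        tr = make_track(y)
        m = backward_eliminate(tr, p)
        assert m.active_jumps()  # survives plain elimination (gap branch)
        c = cleanup(tr, m, p)
        assert c.active_jumps() == []

    def test_all_levels_zero_or_above_floor(self, params_s1):
        track, _ = simulate_track(3000, cnvs=[PlantedCNV(1000, 60, 0.5)], seed=9)
        c = cleanup(track, backward_eliminate(track, params_s1), params_s1)
        for _, _, lev in c.segments():
            assert lev == 0.0 or abs(lev) >= params_s1.mu_min


class TestConsolidate:
    def test_weighted_average_intensity(self, params_s1):
        y = np.concatenate([np.zeros(20), np.full(100, 0.6), np.full(30, 0.3), np.zeros(20)])
        tr = make_track(y)
        calls = call_track(tr, params_s1)
        assert len(calls) == 1
        c = calls[0]
        assert c.m == 130
        assert c.intensity == pytest.approx((100 * 0.6 + 30 * 0.3) / 130)
        assert c.score == pytest.approx(abs(c.intensity) * 130**0.5)

    def test_sign_change_splits_adjacent_calls(self, params_s1):
        y = np.concatenate([np.zeros(15), np.full(20, 0.4), np.full(20, -0.4), np.zeros(15)])
        calls = call_track(make_track(y), params_s1)
        assert len(calls) == 2
        assert calls[0].sign == 1 and calls[1].sign == -1
        assert calls[0].end_idx + 1 == calls[1].start_idx

    def test_noiseless_cnv_call(self, noiseless_cnv_track, params_s1):
        calls = call_track(noiseless_cnv_track, params_s1)
        assert len(calls) == 1
        c = calls[0]
        assert (c.start_idx, c.end_idx, c.m) == (11, 20, 10)
        assert c.intensity == pytest.approx(0.6)
        assert c.median_lir == pytest.approx(0.6)
        assert c.score == pytest.approx(0.6 * np.sqrt(10), rel=1e-9)
        assert c.start_bp == 11 * 50 and c.end_bp == 20 * 50

    def test_emitted_calls_satisfy_contract(self):
        p = CutoffParams(score_min=2.0)
        for seed in range(5):
            track, _ = simulate_track(
                4000, cnvs=[PlantedCNV(1000, 50, 0.5), PlantedCNV(2500, 80, -0.6)], seed=seed
            )
            for c in call_track(track, p):
                assert c.m >= p.m_min
                assert c.score >= p.score_min
                assert c.m <= p.m_max or abs(c.intensity) >= p.mu_min

    def test_deterministic(self, params_s1):
        track, _ = simulate_track(2000, cnvs=[PlantedCNV(900, 50, 0.5)], seed=17)
        assert call_track(track, params_s1) == call_track(track, params_s1)


class TestLeastSquaresVariant:
    def test_l2_levels_are_means(self, params_s1):
        y = np.array([0.0] * 10 + [0.2, 0.9, 0.4, 0.5, 0.2, 0.9, 0.4, 0.5, 0.2, 0.9] + [0.0] * 10)
        m = JumpModel(y, params_s1, jumps=[10, 20], objective="l2")
        assert m.level_r[10] == pytest.approx(np.mean(y[10:20]))
        m1 = JumpModel(y, params_s1, jumps=[10, 20], objective="l1")
        assert m1.level_r[10] == pytest.approx(np.median(y[10:20]))
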