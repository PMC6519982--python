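import numpy as np
import pytest

from vesiclekit import (
    QuantalTrain,
    ReleaseModelParams,
    bin_release,
    differential_release,
    jump_recruitment,
    make_protocol,
    normalized_cumulative_differential,
    paired_pulse_ratio,
    pv_from_jump,
    recovery_fraction,
    simulate_averaged_train,
    standing_fullness,
)
from vesiclekit.analyses import InvalidPairingError
from vesiclekit.kinetics import RecruitmentRateFunction


class TestBinRelease:
    def test_50hz_one_stimulus_per_bin(self):
        proto = make_protocol([(50.0, 10)])
        train = QuantalTrain(proto.stim_times, np.arange(10.0))
        binned = bin_release(train, 0.020)
        np.testing.assert_allclose(binned, np.arange(10.0))

    def test_300hz_six_stimuli_per_bin(self):
        proto = make_protocol([(300.0, 12)])
        train = QuantalTrain(proto.stim_times, np.ones(12))
        binned = bin_release(train, 0.020)
        np.testing.assert_allclose(binned, [6.0, 6.0])

    def test_empty_train(self):
        train = QuantalTrain(np.array([]), np.array([]))
        assert bin_release(train, 0.020).size == 0


def make_jump_pair(pv_low=0.2, first=100.0, n_jump=40):
    """Geometric differential decay: conditioning + 300 Hz jump where the
    jump releases first*(1-p)^k extra and the control stays flat."""
    cond = make_protocol([(50.0, 20)])
    jump_proto = make_protocol([(50.0, 20), (300.0, n_jump)])
    flat = 5.0
    ctrl_proto = make_protocol([(50.0, 20 + 15)])
    d = first * (1 - pv_low) ** np.arange(n_jump)
    jump_q = np.concatenate([np.full(20, flat), d + flat / 6.0])
    ctrl_q = np.full(35, flat)
    return (QuantalTrain(jump_proto.stim_times, jump_q),
            QuantalTrain(ctrl_proto.stim_times, ctrl_q),
            jump_proto.stim_times[20])


class TestDifferentialRelease:
    def test_identical_trials_give_zero_differential(self):
        proto = make_protocol([(50.0, 30)])
        train = QuantalTrain(proto.stim_times, np.full(30, 8.0))
        res = differential_release(train, train, proto.stim_times[15])
        np.testing.assert_allclose(res.differential, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.per_stimulus_differential, 0.0,
                                   atol=1e-12)

    def test_mismatched_prejump_protocols_rejected(self):
        a = QuantalTrain(np.arange(30) / 50.0, np.ones(30))
        b = QuantalTrain(np.arange(30) / 40.0, np.ones(30))
        with pytest.raises(InvalidPairingError):
            differential_release(a, b, 0.3)

    def test_control_flux_allocation(self):
        # control releases 6 quanta per 20 ms -> one 300 Hz interval carries 1
        jump, ctrl, onset = make_jump_pair()
        ctrl.quanta[:] = 6.0
        jump.quanta[:20] = 6.0
        res = differential_release(jump, ctrl, onset)
        expected_first = jump.quanta[20] - 6.0 / 6.0
        assert res.first_differential == pytest.approx(expected_first)


class TestPvFromJump:
    def test_arithmetic_example(self):
        jump, ctrl, onset = make_jump_pair()
        res = differential_release(jump, ctrl, onset)
        res.per_stimulus_differential = np.array([14.4, 200.0, 85.6])
        res.first_differential = 14.4
        pv = pv_from_jump(res, 60.0)
        assert res.rrp_at_jump == pytest.approx(240.0)
        assert pv.pv_bar == pytest.approx(0.06)

    def test_nonpositive_standing_pool_invalid(self):
        jump, ctrl, onset = make_jump_pair()
        res = differential_release(jump, ctrl, onset)
        with pytest.raises(ValueError):
            pv_from_jump(res, 1e9)


class TestNormalizedCumulativeDifferential:
    def test_geometric_intercept_closed_form(self):
        # sum of (1-p)^k = 1/p; no recruitment -> intercept exact
        jump, ctrl, onset = make_jump_pair(pv_low=0.2, n_jump=60)
        res = differential_release(jump, ctrl, onset)
        norm, intercept = normalized_cumulative_differential(res)
        assert intercept == pytest.approx(1 / 0.2, rel=1e-3)
        norm2, intercept2 = normalized_cumulative_differential(res, alpha=0.0)
        assert intercept2 == pytest.approx(1 / 0.2, rel=1e-3)

    def test_scaling_leaves_normalized_curve_unchanged(self):
        jump, ctrl, onset = make_jump_pair()
        res1 = differential_release(jump, ctrl, onset)
        res2 = differential_release(jump.scaled(3.0), ctrl.scaled(3.0), onset)
        n1, _ = normalized_cumulative_differential(res1)
        n2, _ = normalized_cumulative_differential(res2)
        np.testing.assert_allclose(n1, n2, rtol=1e-9)

    def test_zero_first_differential_invalid(self):
        jump, ctrl, onset = make_jump_pair()
        res = differential_release(jump, ctrl, onset)
        res.first_differential = 0.0
        with pytest.raises(ValueError):
            normalized_cumulative_differential(res)


class TestStandingFullness:
    def test_simple_fraction(self):
        assert standing_fullness(240.0, 1200.0) == pytest.approx(0.2)

    def test_higher_frequency_lowers_fullness(self):
        # deterministic steady state of the expectation model
        from vesiclekit.kinetics import expected_occupancy
        f50 = expected_occupancy(1000, 0.1, 1.0, 0.02, 1)[1]
        f100 = expected_occupancy(1000, 0.1, 1.0, 0.01, 1)[1]
        assert f100 < f50

    def test_higher_pv_lowers_fullness(self):
        from vesiclekit.kinetics import expected_occupancy
        lo = expected_occupancy(1000, 0.1, 1.0, 0.02, 1)[1]
        hi = expected_occupancy(1000, 0.2, 1.0, 0.02, 1)[1]
        assert hi < lo


class TestRecovery:
    @staticmethod
    def _paired(rest, seed, alpha=5.4):
        from vesiclekit.reproduce import _paired_train
        rec = RecruitmentRateFunction(alpha, alpha, 2.0, alpha)
        p = ReleaseModelParams(n_high=3200, n_low=0, pv_high=0.4, pv_low=0.0,
                               recruitment=rec)
        return _paired_train(p, rest, seed, 8)

    def test_short_rest_matches_closed_form(self):
        tr1, tr2 = self._paired(0.1, seed=31)
        _, f = recovery_fraction(tr1, tr2, 0.1, alpha=5.4)
        assert f == pytest.approx(1 - np.exp(-0.54), abs=0.05)

    def test_long_rest_full_recovery(self):
        tr1, tr2 = self._paired(60.0, seed=33)
        _, f = recovery_fraction(tr1, tr2, 60.0, alpha=5.4)
        assert f == pytest.approx(1.0, abs=0.05)

    def test_fullness_nondecreasing_in_rest(self):
        fs = []
        for rest, seed in ((0.1, 41), (0.5, 42), (4.0, 43)):
            tr1, tr2 = self._paired(rest, seed)
            fs.append(recovery_fraction(tr1, tr2, rest, alpha=5.4)[1])
        assert fs[0] < fs[1] < fs[2]


class TestPairedPulseRatio:
    def test_simple_ratio(self):
        train = QuantalTrain(np.array([0.0, 0.05]), np.array([50.0, 60.0]))
        res = paired_pulse_ratio(train)
        assert res.ratio == pytest.approx(1.2)
        assert res.inter_pulse == pytest.approx(0.05)
        assert res.facilitating

    def test_depression_without_facilitation(self):
        rec = RecruitmentRateFunction(alpha_train=0.25)
        p = ReleaseModelParams(n_high=200, n_low=200, pv_high=0.2, pv_low=0.05,
                               recruitment=rec)
        proto = make_protocol([(20.0, 2)])
        train = simulate_averaged_train(p, proto, 500, seed=55)
        assert paired_pulse_ratio(train).ratio < 1.0

    def test_facilitation_unmasked_by_lowering_pv(self):
        rec = RecruitmentRateFunction(alpha_train=0.25)
        base = dict(n_high=200, n_low=200, recruitment=rec,
                    facilitation_increment=0.45, facilitation_tau=0.1)
        proto = make_protocol([(20.0, 2)])
        high = ReleaseModelParams(pv_high=0.4, pv_low=0.1, **base)
        low = high.scaled_pv(0.5)
        ppr_high = paired_pulse_ratio(
            simulate_averaged_train(high, proto, 800, seed=56)).ratio
        ppr_low = paired_pulse_ratio(
            simulate_averaged_train(low, proto, 800, seed=57)).ratio
        assert ppr_high < 1.0 < ppr_low

    def test_first_response_zero_invalid(self):
        train = QuantalTrain(np.array([0.0, 0.05]), np.array([0.0, 5.0]))
        with pytest.raises(ValueError):
            paired_pulse_ratio(train)


class TestJumpRecruitmentMethods:
    def test_duration_insensitivity_at_steady_state(self):
        # once the standing pool has settled, extending the 100 Hz
        # conditioning leaves the jump pv estimate unchanged
        out = {}
        rec = RecruitmentRateFunction(alpha_train=1.2)
        params = ReleaseModelParams(n_high=160, n_low=3040, pv_high=0.18,
                                    pv_low=0.06, recruitment=rec)
        for n_cond in (75, 100):
            proto = make_protocol([(100.0, n_cond), (300.0, 60)])
            ctrl = make_protocol([(100.0, n_cond + 23)])
            jt = simulate_averaged_train(params, proto, 100, seed=61)
            ct = simulate_averaged_train(params, ctrl, 100, seed=62)
            res = differential_release(jt, ct, proto.stim_times[n_cond])
            pv = pv_from_jump(res, jump_recruitment(res, 1.2, "M"))
            out[n_cond] = pv.pv_bar
        assert out[75] == pytest.approx(out[100], rel=0.15)

    def test_s_method_nonnegative(self):
        jump, ctrl, onset = make_jump_pair()
        res = differential_release(jump, ctrl, onset)
        assert jump_recruitment(res, 5.0, "S") >= 0.0
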