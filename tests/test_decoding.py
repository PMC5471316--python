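import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy.optimize import brentq

import spikeinfo as si
from spikeinfo.decoding import PosteriorTrace, RateEstimates
from spikeinfo.population import CurrentTrace, SpikeTrain
from spikeinfo.telegraph import HiddenStateTrace, MarkovParams


R_ON, R_OFF = 20 / 3, 40 / 3


def drift_root(r_on, r_off):
    return brentq(lambda l: r_on * (1 + np.exp(-l)) - r_off * (1 + np.exp(l)), -20, 20)


class TestLogOddsIntegration:
    def test_stays_at_drift_equilibrium_when_input_equals_offset(self):
        theta = 3.0
        tr = CurrentTrace(np.full(5000, theta), 2e-4, offset_theta=theta)
        l_eq = drift_root(R_ON, R_OFF)
        post = si.integrate_log_odds_from_input(tr, R_ON, R_OFF, l0=l_eq)
        assert np.allclose(post.L, l_eq, atol=1e-10)

    def test_large_constant_input_saturates_posterior(self):
        # moderate constant drive: monotone rise to the fixed point
        tr = CurrentTrace(np.full(5000, 2e3), 2e-4)
        post = si.integrate_log_odds_from_input(tr, R_ON, R_OFF)
        assert np.all(np.diff(post.L) >= -1e-12)
        assert post.p[-1] > 0.99
        # extreme drive: the stiffness guard keeps L pinned near the fixed
        # point (e^L ~ I/r_off) without oscillation to the clip bounds
        huge = CurrentTrace(np.full(5000, 1e5), 2e-4)
        post = si.integrate_log_odds_from_input(huge, R_ON, R_OFF)
        l_eq = np.log(1e5 / R_OFF)
        assert np.all(post.p[-100:] > 0.999)
        assert np.all(np.abs(post.L[10:] - l_eq) < 1.5)

    def test_rejects_ampere_traces(self):
        tr = CurrentTrace(np.zeros(10), 2e-4, units="ampere")
        with pytest.raises(ValueError):
            si.integrate_log_odds_from_input(tr, R_ON, R_OFF)

    def test_refined_integration_matches_working_step(self, frozen_slow_input):
        """The fixed-step solve at dt agrees with a dt/10 reference solve of
        the same sampled drive (zero-order hold), sampled back to the grid."""
        hidden, _, trace = frozen_slow_input
        post = si.integrate_log_odds_from_input(trace, R_ON, R_OFF)
        m = 10
        fine = CurrentTrace(
            np.repeat(trace.values, m), trace.dt / m, offset_theta=trace.offset_theta
        )
        post_f = si.integrate_log_odds_from_input(fine, R_ON, R_OFF)
        sub = PosteriorTrace(post_f.L[m - 1 :: m], trace.dt, "input")
        mi = si.mutual_information(hidden, post)
        mi_ref = si.mutual_information(hidden, sub)
        assert mi == pytest.approx(mi_ref, rel=0.01)
        assert 0 < mi <= si.empirical_entropy(hidden)


class TestEstimateRates:
    def test_homogeneous_train_recovers_rate_in_both_states(self, rng):
        hidden = si.simulate_hidden_state(MarkovParams(5.0, 10.0, 1e-3, 200.0, seed=1))
        times = np.sort(rng.uniform(0, 200.0, rng.poisson(10.0 * 200)))
        est = si.estimate_rates(SpikeTrain(times, (0.0, 200.0)), hidden)
        t_on = hidden.x.sum() * hidden.dt
        t_off = 200.0 - t_on
        assert abs(est.q_on_hat - 10.0) < 3 * np.sqrt(10.0 / t_on)
        assert abs(est.q_off_hat - 10.0) < 3 * np.sqrt(10.0 / t_off)

    def test_silent_state_rate_is_floored_with_warning(self, short_hidden):
        on_bin = int(np.flatnonzero(short_hidden.x)[10])
        train = SpikeTrain(np.array([on_bin * short_hidden.dt]), (0.0, 5.0))
        with pytest.warns(UserWarning, match="floored"):
            est = si.estimate_rates(train, short_hidden)
        t_off = float((short_hidden.x == 0).sum()) * short_hidden.dt
        assert est.q_off_hat == pytest.approx(1.0 / t_off)
        assert est.w_hat > 0

    def test_single_state_trace_rejected(self):
        hid = HiddenStateTrace(np.ones(100), MarkovParams(1.0, 1.0, 1e-3, 0.1))
        with pytest.raises(ValueError):
            si.estimate_rates(SpikeTrain(np.empty(0), (0.0, 0.1)), hid)

    def test_bias_shrinks_with_duration(self):
        # state-modulated neuron; mean absolute rate error falls with T
        errs = []
        for dur in (20.0, 80.0, 320.0):
            e = []
            for s in range(6):
                hidden = si.simulate_hidden_state(
                    MarkovParams(R_ON, R_OFF, 1e-3, dur, seed=s)
                )
                pop_rng = np.random.default_rng(100 + s)
                n_bins_on = int(hidden.x.sum())
                k_on = pop_rng.binomial(n_bins_on, 8.0 * 1e-3)
                k_off = pop_rng.binomial(hidden.x.size - n_bins_on, 3.0 * 1e-3)
                on_bins = np.flatnonzero(hidden.x == 1)
                off_bins = np.flatnonzero(hidden.x == 0)
                bins = np.sort(
                    np.r_[
                        pop_rng.choice(on_bins, k_on, replace=False),
                        pop_rng.choice(off_bins, k_off, replace=False),
                    ]
                )
                train = SpikeTrain(bins * 1e-3, (0.0, dur))
                est = si.estimate_rates(train, hidden)
                e.append(abs(est.q_on_hat - 8.0) + abs(est.q_off_hat - 3.0))
            errs.append(np.mean(e))
        assert errs[2] < errs[0]


class TestSpikeTrainDrive:
    def test_impulse_amplitude_and_integral(self):
        train = SpikeTrain(np.array([0.01]), (0.0, 0.1))
        est = RateEstimates(10.0, 10.0 / np.exp(2.0))
        drive = si.spike_train_drive(train, est, 2e-4)
        assert drive.values[50] == pytest.approx(2.0 / 2e-4)
        assert np.count_nonzero(drive.values) == 1
        assert drive.values.sum() * 2e-4 == pytest.approx(2.0)
        assert drive.offset_theta == pytest.approx(est.theta_hat)

    def test_integral_scales_with_spike_count(self, rng):
        times = np.sort(rng.uniform(0, 1.0, 50))
        est = RateEstimates(20.0, 5.0)
        drive = si.spike_train_drive(SpikeTrain(times, (0.0, 1.0)), est, 1e-3)
        assert drive.values.sum() * 1e-3 == pytest.approx(50 * est.w_hat)

    def test_decoder_tracks_encoder_output_log_odds(self, frozen_slow_input):
        """Decoding the optimal encoder's spikes reproduces a close match of
        its own output log-odds G between spikes."""
        hidden, _, trace = frozen_slow_input
        train, hist = si.simulate_bn(
            trace, si.BNParams(R_ON, R_OFF, trace.offset_theta, 2.0, trace.dt)
        )
        post, _ = si.decode_spike_train(train, hidden)
        corr = np.corrcoef(post.L, hist.G)[0, 1]
        assert corr > 0.9


class TestEntropyAndInformation:
    def test_prior_posterior_gives_zero_information(self, short_hidden):
        p = np.full(short_hidden.x.size, short_hidden.occupancy)
        h = si.conditional_entropy(short_hidden, p)
        assert h == pytest.approx(si.empirical_entropy(short_hidden), abs=1e-12)
        assert si.mutual_information(short_hidden, p) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_posterior_recovers_full_entropy(self, short_hidden):
        p = short_hidden.x.astype(float)
        assert si.conditional_entropy(short_hidden, p) == pytest.approx(0.0, abs=1e-9)
        mi = si.mutual_information(short_hidden, p)
        assert mi / si.empirical_entropy(short_hidden) == pytest.approx(1.0, abs=1e-9)

    def test_adversarial_posterior_yields_negative_information(self, short_hidden):
        p = 1.0 - short_hidden.x.astype(float)
        assert si.mutual_information(short_hidden, p) < -si.empirical_entropy(
            short_hidden
        )

    def test_length_mismatch_rejected(self, short_hidden):
        with pytest.raises(ValueError):
            si.conditional_entropy(short_hidden, np.full(10, 0.5))

    @settings(derandomize=True, max_examples=50)
    @given(
        hnp.arrays(
            np.float64,
            st.integers(10, 200),
            elements=st.floats(0.001, 0.999),
        ),
        st.integers(0, 2**31 - 1),
    )
    def test_information_never_exceeds_entropy(self, p, seed):
        rng = np.random.default_rng(seed)
        x = (rng.random(p.size) < 0.4).astype(np.uint8)
        assert si.mutual_information(x, p) <= si.empirical_entropy(x) + 1e-12


class TestMseMeasures:
    def test_perfect_estimate_has_zero_error(self, short_hidden):
        p = short_hidden.x.astype(float)
        assert si.mse(short_hidden, p) == pytest.approx(0.0, abs=1e-12)

    def test_constant_prior_estimate_equals_state_variance(self, short_hidden):
        p1 = short_hidden.occupancy
        p = np.full(short_hidden.x.size, p1)
        assert si.mse(short_hidden, p) == pytest.approx(p1 * (1 - p1))

    def test_poisson_surrogate_self_normalizes_to_one(self, frozen_slow_input):
        hidden, _, _ = frozen_slow_input
        rng = np.random.default_rng(5)
        surr = SpikeTrain(np.sort(rng.uniform(0, 20.0, 240)), (0.0, 20.0))
        post, _ = si.decode_spike_train(surr, hidden)
        _, mse_p, _ = si.mse_measures(
            hidden, post, spikes=surr, n_poisson=40, seed=9
        )
        assert mse_p == pytest.approx(1.0, abs=0.15)


class TestShiftCorrect:
    def test_constructed_delay_is_recovered(self, short_hidden):
        d = 15  # 3 ms at 0.2 ms bins
        x = short_hidden.x.astype(float)
        delayed = np.r_[np.full(d, x.mean()), x[:-d]]
        post = PosteriorTrace(np.log(np.clip(delayed, 1e-9, 1 - 1e-9) /
                                     (1 - np.clip(delayed, 1e-9, 1 - 1e-9))),
                              short_hidden.dt)
        lag, mi_star = si.shift_correct(short_hidden, post)
        assert lag == pytest.approx(d * short_hidden.dt)
        assert mi_star == pytest.approx(si.empirical_entropy(short_hidden), rel=0.01)

    def test_zero_delay_gives_zero_lag(self, short_hidden):
        x = np.clip(short_hidden.x.astype(float), 1e-9, 1 - 1e-9)
        post = PosteriorTrace(np.log(x / (1 - x)), short_hidden.dt)
        lag, mi_star = si.shift_correct(short_hidden, post)
        assert lag == 0.0
        assert mi_star == pytest.approx(si.mutual_information(short_hidden, post))

    def test_flat_correlogram_warns(self, short_hidden):
        post = PosteriorTrace(np.zeros(short_hidden.x.size), short_hidden.dt)
        with pytest.warns(UserWarning, match="flat"):
            lag, _ = si.shift_correct(short_hidden, post)
        assert lag == 0.0

    def test_shift_correction_rarely_loses_information(self):
        reg = si.get_regime("S")
        wins = 0
        for s in range(10):
            hidden, _, trace = si.generate_regime_input(
                reg, N=300, duration=20.0, seed=np.random.SeedSequence([13, s])
            )
            post = si.integrate_log_odds_from_input(trace, reg.r_on, reg.r_off)
            mi = si.mutual_information(hidden, post)
            _, mi_star = si.shift_correct(hidden, post)
            wins += mi_star >= mi - 1e-6
        assert wins >= 9
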