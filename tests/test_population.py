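import numpy as np
import pytest

import spikeinfo as si
from spikeinfo.population import (
    CurrentTrace,
    KernelSpec,
    PresynapticPopulation,
    ScalingParams,
    SpikeTrain,
)
from spikeinfo.telegraph import HiddenStateTrace, MarkovParams


def make_pop(q_on, q_off, mu_q=1.0, w=None):
    q_on = np.atleast_1d(np.asarray(q_on, float))
    q_off = np.atleast_1d(np.asarray(q_off, float))
    if w is None:
        w = np.log(q_on / q_off)
    return PresynapticPopulation(
        q_on, q_off, np.atleast_1d(w), mu_q, mu_q / 8, float(np.sum(q_on - q_off))
    )


class TestDrawPopulation:
    def test_rate_distribution_matches_requested_moments(self):
        pop = si.draw_population(1000, 0.5, seed=0)
        se_mean = 0.0625 / np.sqrt(1000)
        se_sd = 0.0625 / np.sqrt(2 * 1000)
        assert abs(pop.q_on.mean() - 0.5) < 3 * se_mean
        assert abs(pop.q_on.std(ddof=1) - 0.0625) < 3 * se_sd
        assert np.all(pop.q_on > 0) and np.all(pop.q_off > 0)

    def test_weights_and_offset_satisfy_invariants(self):
        pop = si.draw_population(200, 2.5, seed=1)
        assert np.allclose(pop.w, np.log(pop.q_on / pop.q_off))
        assert pop.theta == pytest.approx(np.sum(pop.q_on - pop.q_off))
        assert pop.sigma_q == pytest.approx(pop.mu_q / 8)

    def test_zero_theta_switch(self):
        pop = si.draw_population(200, 2.5, seed=1, zero_theta=True)
        assert pop.theta == 0.0

    def test_weight_identities(self):
        assert make_pop(5.0, 5.0).w[0] == 0.0
        assert make_pop(5.0 * np.e, 5.0).w[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [dict(N=0, mu_q=1.0), dict(N=10, mu_q=0.0)])
    def test_invalid_arguments_rejected(self, bad):
        with pytest.raises(ValueError):
            si.draw_population(seed=0, **bad)

    def test_informative_drive_is_nonnegative(self):
        # sum_i w_i (q_on_i - q_off_i): each term is (log a - log b)(a - b) >= 0
        pop = si.draw_population(500, 1.3, seed=3)
        assert np.sum(pop.w * (pop.q_on - pop.q_off)) >= 0


class TestGeneratePopulationSpikes:
    def test_state_independent_neuron_has_poisson_count(self, rng):
        hidden = si.simulate_hidden_state(MarkovParams(5.0, 10.0, 1e-3, 100.0, seed=4))
        pop = make_pop(5.0, 5.0, mu_q=5.0)
        (train,) = si.generate_population_spikes(pop, hidden, seed=5)
        assert abs(train.n_spikes - 500) < 3 * np.sqrt(500)

    def test_silent_when_off_if_off_rate_zero(self):
        hidden = si.simulate_hidden_state(MarkovParams(5.0, 10.0, 1e-3, 50.0, seed=4))
        pop = make_pop(5.0, 0.0, mu_q=5.0, w=[0.0])
        (train,) = si.generate_population_spikes(pop, hidden, seed=5)
        bins = train.bin_indices(hidden.dt)
        assert np.all(hidden.x[bins] == 1)

    def test_pooled_on_rate_matches_superposition(self):
        reg = si.get_regime("F")
        hidden = si.simulate_hidden_state(reg.markov_params(2e-4, 20.0, seed=6))
        pop = si.draw_population(300, reg.mu_q, seed=6)
        trains = si.generate_population_spikes(pop, hidden, seed=7)
        t_on = hidden.x.sum() * hidden.dt
        n_on = sum(
            int(hidden.x[t.bin_indices(hidden.dt)].sum()) for t in trains if t.n_spikes
        )
        expected = pop.q_on.sum() * t_on
        assert abs(n_on - expected) < 3 * np.sqrt(expected)

    def test_determinism_and_rate_limit(self, short_hidden):
        pop = si.draw_population(20, 1.0, seed=8)
        a = si.generate_population_spikes(pop, short_hidden, seed=9)
        b = si.generate_population_spikes(pop, short_hidden, seed=9)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.times, tb.times)
        fast = make_pop(6000.0, 6000.0, mu_q=6000.0)
        with pytest.raises(ValueError, match="refine dt"):
            si.generate_population_spikes(fast, short_hidden, seed=9)


class TestKernel:
    def test_unit_area_and_efold(self):
        k = si.exponential_kernel(KernelSpec(0.005), 2e-4)
        assert k.sum() * 2e-4 == pytest.approx(1.0, abs=1e-12)
        assert k[0] / k[25] == pytest.approx(np.e, abs=1e-9)

    def test_undersampled_kernel_rejected(self):
        with pytest.raises(ValueError):
            si.exponential_kernel(KernelSpec(0.005), 0.005)

    def test_single_spike_convolution_has_unit_integral(self, short_hidden):
        pop = make_pop(2.0, 2.0, w=[1.0], mu_q=2.0)
        train = SpikeTrain(np.array([1.0]), (0.0, 5.0))
        trace = si.build_input(pop, [train], KernelSpec(), dt=2e-4)
        assert trace.values.sum() * 2e-4 == pytest.approx(1.0, abs=1e-9)


class TestBuildInput:
    def test_empty_trains_give_zero_trace(self):
        pop = make_pop([2.0, 2.0], [2.0, 2.0], mu_q=2.0)
        trains = [SpikeTrain(np.empty(0), (0.0, 1.0))] * 2
        trace = si.build_input(pop, trains, dt=1e-3)
        assert np.all(trace.values == 0.0)

    def test_single_spike_is_weighted_shifted_kernel(self):
        w = -1.7
        pop = make_pop(2.0, 2.0, w=[w], mu_q=2.0)
        train = SpikeTrain(np.array([0.01]), (0.0, 0.2))
        trace = si.build_input(pop, [train], dt=1e-3)
        k = si.exponential_kernel(KernelSpec(), 1e-3)
        expected = np.zeros(200)
        expected[10 : 10 + k.size] = w * k[: 200 - 10]
        assert np.allclose(trace.values, expected)

    def test_superposition_of_subpopulations(self, rng):
        hidden = si.simulate_hidden_state(MarkovParams(5.0, 10.0, 1e-3, 5.0, seed=1))
        pa = si.draw_population(10, 1.0, seed=2)
        pb = si.draw_population(15, 2.0, seed=3)
        sa = si.generate_population_spikes(pa, hidden, seed=4)
        sb = si.generate_population_spikes(pb, hidden, seed=5)
        union = PresynapticPopulation(
            np.r_[pa.q_on, pb.q_on],
            np.r_[pa.q_off, pb.q_off],
            np.r_[pa.w, pb.w],
            1.0,
            0.125,
            pa.theta + pb.theta,
        )
        t_union = si.build_input(union, sa + sb, dt=1e-3)
        t_a = si.build_input(pa, sa, dt=1e-3)
        t_b = si.build_input(pb, sb, dt=1e-3)
        assert np.allclose(t_union.values, t_a.values + t_b.values)

    def test_mismatched_windows_rejected(self):
        pop = make_pop([2.0, 2.0], [2.0, 2.0], mu_q=2.0)
        trains = [
            SpikeTrain(np.empty(0), (0.0, 1.0)),
            SpikeTrain(np.empty(0), (0.0, 2.0)),
        ]
        with pytest.raises(ValueError, match="window"):
            si.build_input(pop, trains, dt=1e-3)


class TestScaleCurrent:
    def test_identity_and_offset(self):
        tr = CurrentTrace(np.array([0.0, 1.0, -1.0]), 1e-3)
        out = si.scale_current(tr, ScalingParams(0.0, 1.0))
        assert np.allclose(out.values, tr.values)
        assert out.units == "ampere"
        const = si.scale_current(
            CurrentTrace(np.zeros(5), 1e-3), ScalingParams(50e-12, 250e-12)
        )
        assert np.allclose(const.values, 50e-12)

    def test_double_scaling_rejected(self):
        tr = CurrentTrace(np.zeros(5), 1e-3)
        out = si.scale_current(tr, ScalingParams(0.0, 250e-12))
        with pytest.raises(ValueError, match="double-scale"):
            si.scale_current(out, ScalingParams(0.0, 500e-12))

    @pytest.mark.parametrize("pa", [250, 500, 750, 1000, 1250])
    def test_standard_scan_grid_accepted(self, pa):
        ScalingParams(0.0, pa * 1e-12)


class TestInputStatistics:
    def test_autocorrelation_time_grows_with_tau(self):
        def ac_time(tau):
            reg = si.RegimeSpec("t", 1 / (3 * tau), 2 / (3 * tau), 2.0)
            _, _, trace = si.generate_regime_input(reg, N=200, duration=10.0, seed=1)
            v = trace.values - trace.values.mean()
            ac = np.correlate(v, v, "full")[v.size - 1 :]
            ac /= ac[0]
            return np.argmax(ac < np.exp(-1))

        assert ac_time(0.1) > ac_time(0.01)

    def test_variance_grows_with_mu_q(self):
        def var(mu):
            reg = si.RegimeSpec("t", 20 / 3, 40 / 3, mu)
            _, _, trace = si.generate_regime_input(reg, N=200, duration=10.0, seed=1)
            return trace.values.var()

        assert var(2.5) > var(0.5)
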