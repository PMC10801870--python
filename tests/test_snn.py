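"""Spiking-network engine: integration, spiking, rates, smoothing."""

import numpy as np
import pytest

from hetsnn.connectivity import ConnectivitySpec, build_connectivity
from hetsnn.snn import (IntegratorConfig, SpikeRaster, StimulusProtocol,
                        StimulusSegment, default_integrator, population_rate,
                        run_snn, smooth_single_neuron_rates,
                        SimulationBlowupError)


class TestSingleNeuron:
    def test_rest_is_invariant(self, rs, zero_coupling):
        """At v = vr with no drive, all derivative terms vanish exactly."""
        res = run_snn(rs, np.full(2, rs.vtheta_bar), zero_coupling(2),
                      StimulusProtocol(0.0), duration=100.0)
        assert len(res.raster) == 0
        assert np.allclose(res.state.v, rs.vr, atol=1e-12)
        assert np.allclose(res.state.u, 0.0, atol=1e-12)
        assert np.allclose(res.state.s, 0.0, atol=1e-12)

    def test_driven_isi_converges_under_step_refinement(self, rs, zero_coupling):
        """Inter-spike interval at dt=0.01 ms within 1% of dt=0.001 ms."""
        isis = {}
        for dt in (0.01, 0.001):
            integ = IntegratorConfig(dt=dt, vp=200.0, v0=-300.0)
            res = run_snn(rs, np.full(1, rs.vtheta_bar) - 0.0, zero_coupling(1),
                          StimulusProtocol(200.0), integ, duration=500.0)
            isis[dt] = np.diff(res.raster.spikes_of(0)).mean()
        assert isis[0.01] == pytest.approx(isis[0.001], rel=0.01)

    def test_spike_count_equals_reset_events(self, rs, zero_coupling):
        res = run_snn(rs, np.full(1, rs.vtheta_bar), zero_coupling(1),
                      StimulusProtocol(200.0), duration=300.0)
        # every recorded spike is a reset: the trace never exceeds vp and
        # the rate series integrates to the raster count
        total = res.rate["rate_0"].sum() * 1.0 * 1  # bins of 1 ms, N=1
        assert int(round(total)) == len(res.raster)

    def test_blowup_reported_with_step(self, rs, zero_coupling):
        # with the spike cutoff disabled the quadratic runs away
        integ = IntegratorConfig(dt=0.5, vp=np.inf, v0=-300.0)
        with pytest.raises(SimulationBlowupError, match="step"):
            run_snn(rs, np.full(1, rs.vtheta_bar), zero_coupling(1),
                    StimulusProtocol(500.0), integ, duration=200.0)


class TestNetwork:
    def test_permutation_symmetry_without_disorder(self, rs):
        """Identical all-to-all neurons with equal thresholds stay identical."""
        cm = build_connectivity(
            ConnectivitySpec(4, "all_to_all", 1.0, allow_self=True, seed=0),
            rs.J)
        res = run_snn(rs, np.full(4, rs.vtheta_bar), cm,
                      StimulusProtocol(150.0), duration=300.0)
        assert np.ptp(res.state.v) == 0.0
        counts = [len(res.raster.spikes_of(i)) for i in range(4)]
        assert len(set(counts)) == 1 and counts[0] > 0

    def test_network_rate_stable_under_dt_halving(self, rs, small_sparse_net,
                                                  rs_disorder):
        from hetsnn.params import sample_thresholds
        th = sample_thresholds(rs_disorder, 200)
        rates = {}
        for dt in (0.01, 0.005):
            integ = IntegratorConfig(dt=dt, vp=200.0, v0=-300.0)
            res = run_snn(rs, th, small_sparse_net, StimulusProtocol(60.0),
                          integ, duration=1000.0)
            pr = res.rate
            rates[dt] = pr[pr.time_ms > 500]["rate_0"].mean()
        assert rates[0.01] == pytest.approx(rates[0.005], rel=0.02)

    def test_default_integrator_symmetric_about_vertex(self, rs):
        integ = default_integrator(rs)
        vertex = (rs.vr + rs.vtheta_bar) / 2
        assert integ.vp - vertex == pytest.approx(vertex - integ.v0)


class TestStimulus:
    def test_current_trace_waveforms(self):
        seg_ramp = StimulusSegment(100.0, 200.0, 10.0, waveform="ramp")
        seg_sin = StimulusSegment(0.0, 1000.0, 2.0, waveform="sinusoid",
                                  frequency=10.0)
        stim = StimulusProtocol(5.0, (seg_ramp, seg_sin))
        t = np.array([0.0, 25.0, 150.0])
        out = stim.current_trace(t)
        expect = 5.0 + 2.0 * np.sin(2 * np.pi * 10.0 * t * 1e-3)
        expect[2] += 10.0 * 0.5
        assert np.allclose(out, expect)

    def test_invalid_segment_rejected(self):
        with pytest.raises(ValueError):
            StimulusSegment(10.0, 5.0, 1.0)


class TestRates:
    def test_population_rate_counts(self):
        raster = SpikeRaster(np.array([0, 1, 1]), np.array([5.0, 5.0, 15.0]),
                             n_neurons=2, duration=20.0)
        pr = population_rate(raster, bin=10.0)
        assert np.allclose(pr["rate"], [0.1, 0.05])
        assert np.allclose(pr["rate_hz"], [100.0, 50.0])

    def test_empty_raster_gives_zeros(self):
        raster = SpikeRaster(np.array([], dtype=int), np.array([]), 3, 50.0)
        assert np.all(population_rate(raster, 10.0)["rate"] == 0.0)

    def test_single_neuron_periodic_rate(self):
        times = np.arange(0.0, 100.0, 10.0)
        raster = SpikeRaster(np.zeros(len(times), dtype=int), times, 1, 100.0)
        pr = population_rate(raster, bin=100.0)
        assert pr["rate"].iloc[0] == pytest.approx(0.1)


class TestSmoothing:
    def test_single_spike_gives_unit_area_kernel(self):
        raster = SpikeRaster(np.array([0]), np.array([50.0]), 1, 100.0)
        out = smooth_single_neuron_rates(raster, fs=10.0, sigma=20.0)
        assert out.shape == (1, 1000)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.argmax(out[0]) == 500

    def test_silent_neuron_row_is_zero(self):
        raster = SpikeRaster(np.array([1]), np.array([50.0]), 2, 100.0)
        out = smooth_single_neuron_rates(raster, fs=10.0, sigma=20.0)
        assert np.all(out[0] == 0.0)

    def test_two_far_spikes_superpose(self):
        raster = SpikeRaster(np.array([0, 0]), np.array([100.0, 300.0]),
                             1, 400.0)
        out = smooth_single_neuron_rates(raster, fs=10.0, sigma=20.0)
        assert out.sum() == pytest.approx(2.0, abs=1e-6)
        # non-overlapping kernels: each half carries unit mass
        assert out[0, :2000].sum() == pytest.approx(1.0, abs=1e-6)
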