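import math

import numpy as np
import pytest

from dgephys import intrinsic, simulate
from dgephys.intrinsic import SpikeTrain, block_contingency
from dgephys.model import StepProtocol, Sweep, ValidationError


def _gaussian_spike_sweep(height_mV=100.0, sigma_ms=0.5, baseline_mV=-70.0,
                          fs=100_000.0):
    """One isolated Gaussian 'action potential' on a flat baseline inside
    a step window (fine sampling so the closed-form FWHM is resolved)."""
    proto = StepProtocol(0, 0, 10, step_duration_s=0.5, step_onset_s=0.1)
    t = np.arange(0, 0.7, 1 / fs)
    v = baseline_mV + height_mV * np.exp(
        -0.5 * ((t - 0.3) / (sigma_ms * 1e-3)) ** 2)
    return Sweep(samples=v, sampling_rate=fs,
                 channel_kind="current_clamp_voltage", protocol=proto,
                 metadata={"step_current_pA": 0.0})


class TestDetectSpikes:
    def test_subthreshold_sweep_empty(self):
        proto = StepProtocol(0, 0, 10)
        v = np.full(int(2.4e4), -70.0)
        sw = Sweep(samples=v, channel_kind="current_clamp_voltage",
                   protocol=proto, metadata={"step_current_pA": 0.0})
        assert intrinsic.detect_spikes(sw).n_spikes == 0

    def test_simulator_truth_counts_recovered(self):
        exp, truth = simulate.simulate_fi_sweeps(seed=0)
        fi = intrinsic.fi_curve(exp)
        for current, times in truth.spike_times_per_step.items():
            assert fi.trains[current].n_spikes == times.size

    def test_rate_is_count_over_duration(self):
        exp, _ = simulate.simulate_fi_sweeps(seed=0)
        fi = intrinsic.fi_curve(exp)
        tbl = fi.rates()
        np.testing.assert_allclose(tbl["rate_Hz"], tbl["n_spikes"] / 1.0)

    def test_requires_current_clamp(self):
        sw = Sweep(samples=np.zeros(1000), channel_kind="voltage_clamp_current")
        with pytest.raises(ValidationError):
            intrinsic.detect_spikes(sw, window_s=(0.0, 0.1))


class TestFICurve:
    def test_rheobase_matches_closed_form(self, lif_no_adaptation,
                                          step_protocol_0_300):
        exp, truth = simulate.simulate_fi_sweeps(lif_no_adaptation,
                                                 step_protocol_0_300)
        fi = intrinsic.fi_curve(exp)
        assert abs(fi.rheobase_pA - truth.rheobase_pA) <= 10.0
        assert fi.rheobase_pA == 150.0

    def test_all_subthreshold_missing_rheobase(self):
        p = simulate.NeuronParams(b_pA=0.0, block_enabled=False)
        exp, _ = simulate.simulate_fi_sweeps(p, StepProtocol(-100, 0, 10))
        fi = intrinsic.fi_curve(exp)
        assert fi.rheobase_pA is None
        assert not fi.depol_block_entered

    def test_full_protocol_yields_60_point_table(self):
        exp, _ = simulate.simulate_fi_sweeps(seed=0)
        assert len(intrinsic.fi_curve(exp).rates()) == 60

    def test_max_rate_tie_broken_to_lowest_current(self):
        fi = intrinsic.FIResult(step_duration_s=1.0)
        for I, n in ((100.0, 5), (110.0, 10), (120.0, 10)):
            fi.trains[I] = SpikeTrain(I, np.linspace(0.05, 0.95, n),
                                      np.full(n, 30.0))
            fi.last_spike_time_per_step_s[I] = 0.95
        tbl = fi.rates()
        imax = int(np.argmax(tbl["rate_Hz"].to_numpy()))
        assert tbl["current_pA"].iloc[imax] == 110.0


class TestDepolarizationBlock:
    def test_firing_to_end_not_blocked(self):
        fi = intrinsic.FIResult(rheobase_pA=100.0, current_at_max_rate_pA=200.0)
        fi.last_spike_time_per_step_s = {100.0: 0.95, 150.0: 0.97, 200.0: 0.99}
        flag, cur = intrinsic.depolarization_block(fi)
        assert not flag and cur is None

    def test_simulator_block_truth(self):
        exp, _ = simulate.simulate_fi_sweeps(seed=0)
        fi = intrinsic.fi_curve(exp)
        assert fi.depol_block_entered
        # reported current is the lowest truncated step at/above the F-I peak
        truncated = sorted(I for I, t in fi.last_spike_time_per_step_s.items()
                           if I >= fi.current_at_max_rate_pA
                           and t is not None and t < 0.9)
        assert fi.depol_block_current_pA == truncated[0]

    def test_no_block_when_gate_disabled(self, lif_no_adaptation):
        exp, _ = simulate.simulate_fi_sweeps(lif_no_adaptation,
                                             StepProtocol(0, 300, 10))
        fi = intrinsic.fi_curve(exp)
        assert not fi.depol_block_entered

    def test_cohort_contingency_table(self):
        """Cohorts of 9 WT (7 blocked) and 10 KO (10 blocked) reproduce the
        reference 2x2 table, conserving cell counts."""
        flags = {"WT": [True] * 7 + [False] * 2, "KO": [True] * 10}
        tbl = block_contingency(flags)
        assert tbl.loc["WT"].tolist() == [7, 2]
        assert tbl.loc["KO"].tolist() == [10, 0]
        assert tbl.sum(axis=1).tolist() == [9, 10]


class TestAPFeatures:
    def test_gaussian_closed_form(self):
        """Gaussian spike of height 100 mV, sigma 0.5 ms: prominence is the
        height and the width at half prominence is the FWHM 2.3548*sigma."""
        sw = _gaussian_spike_sweep()
        f = intrinsic.ap_features(sw, spike_time_s=0.2)  # 0.3 s - onset 0.1
        assert f.prominence_mV == pytest.approx(100.0, abs=0.1)
        fwhm = 2 * math.sqrt(2 * math.log(2)) * 0.5
        assert f.half_width_ms == pytest.approx(fwhm, abs=0.01)

    def test_dc_offset_invariance(self):
        sw = _gaussian_spike_sweep(baseline_mV=-70.0)
        sw2 = _gaussian_spike_sweep(baseline_mV=-50.0)
        f1 = intrinsic.ap_features(sw, spike_time_s=0.2)
        f2 = intrinsic.ap_features(sw2, spike_time_s=0.2)
        assert f1.prominence_mV == pytest.approx(f2.prominence_mV, abs=1e-9)
        assert f1.half_width_ms == pytest.approx(f2.half_width_ms, abs=1e-9)

    def test_height_doubling(self):
        f1 = intrinsic.ap_features(_gaussian_spike_sweep(100.0), 0.2)
        f2 = intrinsic.ap_features(_gaussian_spike_sweep(200.0), 0.2)
        assert f2.prominence_mV == pytest.approx(2 * f1.prominence_mV, rel=1e-6)
        assert f2.half_width_ms == pytest.approx(f1.half_width_ms, abs=1e-6)

    def test_clipped_peak_flagged(self):
        sw = _gaussian_spike_sweep()
        v = sw.samples.copy()
        v[v > 0] = 0.0  # saturated ADC
        sw2 = Sweep(samples=v, sampling_rate=sw.sampling_rate,
                    channel_kind=sw.channel_kind, protocol=sw.protocol,
                    metadata=sw.metadata)
        assert intrinsic.ap_features(sw2, spike_time_s=0.2).unreliable


class TestIsiRatio:
    def test_regular_train_is_one(self):
        tr = SpikeTrain(200.0, np.arange(0.1, 1.0, 0.05), None)
        assert intrinsic.isi_adaptation_ratio(tr) == pytest.approx(1.0)

    def test_first_over_last(self):
        times = np.cumsum([0.1, 0.030, 0.05, 0.07, 0.100])
        tr = SpikeTrain(200.0, times, None)
        assert intrinsic.isi_adaptation_ratio(tr) == pytest.approx(0.3)

    def test_two_spikes_missing(self):
        tr = SpikeTrain(200.0, np.array([0.1, 0.2]), None)
        assert intrinsic.isi_adaptation_ratio(tr) is None


class TestPassiveProperties:
    def test_ideal_200_mohm_cell(self, lif_no_adaptation):
        p = simulate.NeuronParams(g_L_nS=5.0, b_pA=0, block_enabled=False)
        exp, _ = simulate.simulate_fi_sweeps(p, StepProtocol(-100, -10, 10))
        r = intrinsic.input_resistance(exp)
        assert r == pytest.approx(200.0, rel=1e-6)

    def test_input_resistance_dc_invariant(self):
        p = simulate.NeuronParams(g_L_nS=5.0, b_pA=0, block_enabled=False)
        exp, _ = simulate.simulate_fi_sweeps(p, StepProtocol(-100, -10, 10))
        for sw in exp:
            sw.samples = sw.samples + 13.0
        assert intrinsic.input_resistance(exp) == pytest.approx(200.0, rel=1e-6)

    def test_steps_outside_window_ignored(self):
        p = simulate.NeuronParams(g_L_nS=5.0, b_pA=0, block_enabled=False)
        exp, _ = simulate.simulate_fi_sweeps(p, StepProtocol(-100, -10, 10))
        exp2, _ = simulate.simulate_fi_sweeps(p, StepProtocol(-200, -110, 10))
        both = type(exp)(sweeps=exp.sweeps + exp2.sweeps)
        # same fit as the in-window steps alone
        assert intrinsic.input_resistance(both) == pytest.approx(
            intrinsic.input_resistance(exp), rel=1e-9)

    def test_too_few_steps_error(self):
        p = simulate.NeuronParams(b_pA=0, block_enabled=False)
        exp, _ = simulate.simulate_fi_sweeps(p, StepProtocol(-20, -10, 10))
        with pytest.raises(ValidationError):
            intrinsic.input_resistance(exp)

    def test_resting_potential(self):
        proto = StepProtocol(0, 0, 10)
        sw = Sweep(samples=np.full(24_000, -80.0),
                   channel_kind="current_clamp_voltage", protocol=proto,
                   metadata={"step_current_pA": 0.0})
        assert intrinsic.resting_potential(sw) == pytest.approx(-80.0)

    def test_resting_potential_with_noise(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(20):
            sw = Sweep(samples=-80.0 + rng.normal(0, 1.0, 10_000),
                       channel_kind="current_clamp_voltage")
            vals.append(intrinsic.resting_potential(sw, baseline_s=(0.0, 1.0)))
        assert np.max(np.abs(np.array(vals) + 80.0)) < 0.1

    def test_window_outside_sweep_rejected(self):
        sw = Sweep(samples=np.zeros(1000),
                   channel_kind="current_clamp_voltage")
        with pytest.raises(ValidationError):
            intrinsic.resting_potential(sw, baseline_s=(0.0, 5.0))
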