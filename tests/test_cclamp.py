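"""Current-clamp chain: spike detection, recruitment measures, F-I
construction, SPR/PR segmentation, gains and firing classification."""

from dataclasses import replace

import numpy as np
import pytest

from picquant import (
    FISeries,
    RampSpec,
    SimCellParams,
    SpikeTrain,
    StepSpec,
    TraceSweep,
    ValidationError,
    classify_firing,
    detect_spikes,
    fi_gain,
    instantaneous_fi,
    recruitment_measures,
    segment_spr_pr,
    simulate_cclamp_ramp,
    simulate_cclamp_step,
)
from picquant.cclamp import NON_FIRING, REPETITIVE, extract_cclamp
from picquant.synth import rheobase


def _flat_cc_sweep(n=20000, rate=10000.0, level=-65.0):
    t = np.arange(n) / rate
    return TraceSweep(
        time=t,
        command=np.zeros(n),
        response=np.full(n, level),
        mode="CC",
        sampling_rate=rate,
    )


class TestDetectSpikes:
    def test_subthreshold_sweep_is_empty(self):
        assert len(detect_spikes(_flat_cc_sweep())) == 0

    def test_detects_every_inserted_waveform(self, noiseless_cc_sweep):
        train = detect_spikes(noiseless_cc_sweep)
        inserted = np.asarray(noiseless_cc_sweep.meta["spike_times"])
        assert len(train) == inserted.size

    def test_threshold_voltage_matches_generator(self, noiseless_cc_sweep, noiseless_params):
        train = detect_spikes(noiseless_cc_sweep)
        assert train.threshold_crossing_voltages[0] == pytest.approx(
            noiseless_params.spike_threshold, abs=1.0
        )

    def test_threshold_invariant_to_time_offset_and_resampling(self, noiseless_params):
        """v_threshold shifts by <0.2 mV between 10 and 20 kHz and is
        unaffected by a DC offset of the time axis."""
        rb = rheobase(noiseless_params)
        ramp = RampSpec(0.0, rb + 4.0, (rb + 4.0) / 4.0, baseline_duration=1.0)
        v_th = {}
        for rate in (10000.0, 20000.0):
            sw = simulate_cclamp_ramp(noiseless_params, ramp, rate)
            v_th[rate] = detect_spikes(sw).threshold_crossing_voltages[0]
        assert abs(v_th[10000.0] - v_th[20000.0]) <= 0.2
        sw = simulate_cclamp_ramp(noiseless_params, ramp, 10000.0)
        shifted = TraceSweep(
            time=sw.time + 123.0, command=sw.command, response=sw.response,
            mode="CC", sampling_rate=sw.sampling_rate, protocol=sw.protocol,
        )
        assert (
            detect_spikes(shifted).threshold_crossing_voltages[0]
            == detect_spikes(sw).threshold_crossing_voltages[0]
        )

    def test_rejects_low_sampling_rate(self):
        with pytest.raises(ValidationError):
            detect_spikes(_flat_cc_sweep(n=2000, rate=1000.0))


class TestRecruitment:
    def test_single_spike_collapses_measures(self):
        sw = _flat_cc_sweep()
        sw.command = np.linspace(0, 10, sw.command.size)
        train = SpikeTrain(
            spike_times=np.array([1.0]),
            threshold_crossing_voltages=np.array([-45.0]),
            peak_voltages=np.array([5.0]),
        )
        rec = recruitment_measures(sw, train)
        assert rec["recruitment_current"] == rec["derecruitment_current"]
        assert rec["delta_i"] == 0.0
        assert np.isnan(rec["delta_f"])

    def test_empty_train_gives_missing(self):
        rec = recruitment_measures(_flat_cc_sweep(), SpikeTrain(np.empty(0), np.empty(0), np.empty(0)))
        assert all(np.isnan(v) for v in rec.values())

    def test_noiseless_recruitment_matches_rheobase(self, noiseless_params, noiseless_cc_sweep):
        """First-spike current sits within 0.1 nA of the quasi-static
        rheobase of the model."""
        train = detect_spikes(noiseless_cc_sweep)
        rec = recruitment_measures(noiseless_cc_sweep, train)
        assert rec["recruitment_current"] == pytest.approx(
            rheobase(noiseless_params), abs=0.1
        )

    def test_delta_i_identity(self, noiseless_cc_sweep):
        train = detect_spikes(noiseless_cc_sweep)
        rec = recruitment_measures(noiseless_cc_sweep, train)
        assert rec["delta_i"] == pytest.approx(
            rec["derecruitment_current"] - rec["recruitment_current"], abs=1e-12
        )


class TestInstantaneousFI:
    def test_constant_isi_gives_constant_frequency(self):
        sw = _flat_cc_sweep()
        sw.command = np.linspace(0, 10, sw.command.size)
        times = 0.2 + 0.02 * np.arange(30)
        train = SpikeTrain(times, np.full(30, -45.0), np.full(30, 5.0))
        asc, desc = instantaneous_fi(sw, train)
        assert np.allclose(asc.frequency, 50.0)

    def test_too_few_spikes_empty(self):
        sw = _flat_cc_sweep()
        train = SpikeTrain(np.array([0.1, 0.2]), np.full(2, -45.0), np.full(2, 5.0))
        asc, desc = instantaneous_fi(sw, train)
        assert asc.current.size == 0 and desc.current.size == 0

    def test_symmetric_cell_limbs_mirror(self):
        """No adaptation, no PIC, no noise: ascending and descending F-I
        series are mirror images within one point."""
        p = SimCellParams(
            g_pic=0.0, g_out=0.0, noise_sd_cc=0.0, tau_pic=0.0,
            adapt_increment=0.0, adapt_slow_increment=0.0,
        )
        rb = rheobase(p)
        ramp = RampSpec(0.0, rb + 2.0, (rb + 2.0) / 4.0, baseline_duration=0.5)
        sw = simulate_cclamp_ramp(p, ramp, 10000.0)
        asc, desc = instantaneous_fi(sw, detect_spikes(sw))
        n = min(asc.frequency.size, desc.frequency.size)
        assert abs(asc.frequency.size - desc.frequency.size) <= 1
        # the outermost intervals near recruitment/de-recruitment are the
        # most timing-sensitive; interior points mirror tightly
        a = asc.frequency[-n:][3:]
        d = desc.frequency[:n][::-1][3:]
        np.testing.assert_allclose(a, d, rtol=0.05)


def _two_segment_series(break_current=5.0, slope_lo=25.0, slope_hi=9.0, step=0.1):
    """Piecewise-linear ascending F-I fixture: steep below the break,
    shallow above (time order: low current first)."""
    lo = np.arange(2.0, break_current, step)
    hi = np.arange(break_current, 8.0 + step / 2, step)
    f_break = 30.0
    f_lo = f_break - slope_lo * (break_current - lo)
    f_hi = f_break + slope_hi * (hi - break_current)
    return FISeries(
        current=np.concatenate([lo, hi]),
        frequency=np.concatenate([f_lo, f_hi]),
        limb="asc",
    )


class TestSegmentSprPr:
    def test_perfect_line_covers_whole_series(self):
        I = np.linspace(2, 8, 40)
        fi = FISeries(I, 10 + 9.3 * I, "asc")
        pr = segment_spr_pr(fi)
        assert pr.pr_indices.size == 40
        assert pr.transition_current == pytest.approx(2.0)

    def test_two_segment_break_recovered(self):
        fi = _two_segment_series()
        pr = segment_spr_pr(fi)
        assert pr.transition_current == pytest.approx(5.0, abs=0.2)

    def test_short_series_undefined(self):
        fi = FISeries(np.linspace(2, 3, 4), np.linspace(20, 30, 4), "asc")
        assert segment_spr_pr(fi) is None

    def test_unstable_apex_window_undefined(self):
        rng = np.random.default_rng(0)
        I = np.linspace(2, 8, 30)
        fi = FISeries(I, 40 + rng.normal(0, 30, 30), "asc")
        assert segment_spr_pr(fi) is None


class TestGain:
    def test_exact_line_recovered_to_machine_precision(self):
        I = np.linspace(2, 8, 40)
        fi = FISeries(I, 10 + 9.3 * I, "asc")
        pr = segment_spr_pr(fi)
        assert fi_gain(fi, pr) == pytest.approx(9.3, abs=1e-9)

    def test_noisy_line_slope_within_analytic_ci(self):
        """OLS slope of line + noise falls inside its closed-form 95% CI
        (sanity of the estimator on a known construction)."""
        from picquant.cclamp import PRSegment

        rng = np.random.default_rng(4)
        I = np.linspace(2, 5, 30)
        true = 12.0
        F = 5 + true * I + rng.normal(0, 2.0, 30)
        fi = FISeries(I, F, "asc")
        pr = PRSegment(I[0], F[0], np.arange(30))
        slope = fi_gain(fi, pr)
        se = 2.0 / (np.std(I, ddof=1) * np.sqrt(len(I) - 1))
        assert abs(slope - true) < 2.5 * se

    def test_undefined_pr_gives_missing_gain(self):
        fi = FISeries(np.empty(0), np.empty(0), "asc")
        assert np.isnan(fi_gain(fi, None))


class TestClassifyFiring:
    def test_many_ramp_spikes_repetitive(self):
        train = SpikeTrain(np.linspace(1, 2, 40), np.full(40, -45.0), np.full(40, 5.0))
        assert classify_firing(train) == REPETITIVE

    def test_few_ramp_spikes_with_step_spike_nonfiring(self):
        ramp = SpikeTrain(np.array([1.0, 1.5]), np.full(2, -45.0), np.full(2, 5.0))
        step = SpikeTrain(np.array([0.6]), np.array([-45.0]), np.array([5.0]))
        assert classify_firing(ramp, step) == NON_FIRING

    def test_silent_step_keeps_repetitive_label(self):
        ramp = SpikeTrain(np.array([1.0]), np.array([-45.0]), np.array([5.0]))
        empty = SpikeTrain(np.empty(0), np.empty(0), np.empty(0))
        assert classify_firing(ramp, empty) == REPETITIVE

    def test_simulated_nonfiring_cell_detected(self, noiseless_params):
        """A cell with a barely-suprathreshold ramp but a clearly
        suprathreshold step classifies as non-firing; the same cell with
        an ample ramp is repetitive."""
        p = replace(noiseless_params, g_pic=0.0, g_out=0.0, noise_sd_cc=0.1)
        rb = rheobase(p)
        tight = RampSpec(0.0, 1.02 * rb, 1.02 * rb / 4.0, baseline_duration=0.5)
        ample = RampSpec(0.0, rb + 4.0, (rb + 4.0) / 4.0, baseline_duration=0.5)
        step = StepSpec(0.0, 1.3 * rb, 0.5)
        fim_tight = extract_cclamp(
            simulate_cclamp_ramp(p, tight, 10000.0),
            simulate_cclamp_step(p, step, 10000.0),
        )
        fim_ample = extract_cclamp(simulate_cclamp_ramp(p, ample, 10000.0))
        assert fim_tight.firing_class == NON_FIRING
        assert np.isnan(fim_tight.recruitment_current)
        assert fim_ample.firing_class == REPETITIVE
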