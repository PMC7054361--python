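"""dF/F normalization, responder criterion, and timing metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from turnbias import calcium as ca
from turnbias import synthetic


def labels(n_light=10, n_dark=30, n_light2=0):
    return np.array(["light"] * n_light + ["dark"] * n_dark + ["light"] * n_light2)


def make_dff(values, epoch_labels, s=0.1, rate=1.0):
    values = np.asarray(values, dtype=float)
    return ca.DffTrace(neuron_id="n", dff=values, epoch_labels=epoch_labels,
                       f0=100.0, s=s, frame_rate_hz=rate)


class TestComputeDff:
    def test_constant_trace_is_zero_with_zero_sd(self):
        trace = np.full(40, 100.0)
        dff = ca.compute_dff(trace, labels())
        assert np.allclose(dff.dff, 0.0) and dff.s == 0.0 and dff.f0 == 100.0

    def test_definitional_arithmetic(self):
        trace = np.full(40, 100.0)
        trace[20] = 150.0
        dff = ca.compute_dff(trace, labels())
        assert dff.dff[20] == pytest.approx(0.5)

    @given(st.floats(0.1, 50.0))
    @settings(deadline=None, max_examples=30)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        trace = 100.0 + rng.normal(0, 3, size=40) + np.where(
            np.arange(40) >= 10, 20.0, 0.0
        )
        a = ca.compute_dff(trace, labels())
        b = ca.compute_dff(c * trace, labels())
        np.testing.assert_allclose(a.dff, b.dff, rtol=1e-9, atol=1e-12)
        assert b.s == pytest.approx(a.s)

    def test_trial_averaging_happens_before_normalization(self):
        trials = np.stack([np.full(40, 90.0), np.full(40, 110.0)])
        trials[1, 25] = 160.0
        dff = ca.compute_dff(trials, labels())
        assert dff.f0 == pytest.approx(100.0)
        assert dff.dff[25] == pytest.approx(0.25)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="F0"):
            ca.compute_dff(np.zeros(40), labels())

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ca.compute_dff(np.ones(30), labels())


class TestClassifyResponder:
    def test_three_dark_frames_above_threshold_are_off(self):
        dff = np.zeros(40)
        dff[15:18] = 0.4  # 4S with S = 0.1
        call = ca.classify_responder(make_dff(dff, labels()))
        assert call.cls == "OFF" and call.onset_frame == 15

    def test_two_frames_do_not_qualify(self):
        dff = np.zeros(40)
        dff[15:17] = 1.0  # 10S, but only two successive frames
        call = ca.classify_responder(make_dff(dff, labels()))
        assert call.cls == "none" and call.onset_frame == -1

    def test_light_after_dark_onset_is_on(self):
        lab = labels(10, 20, 10)
        dff = np.zeros(40)
        dff[31:34] = 0.5
        call = ca.classify_responder(make_dff(dff, lab))
        assert call.cls == "ON"

    def test_baseline_excursion_is_not_a_light_response(self):
        dff = np.zeros(40)
        dff[2:6] = 0.5  # inside the first light epoch
        call = ca.classify_responder(make_dff(dff, labels()))
        assert call.cls == "none" and call.onset_frame == 2

    def test_zero_sd_nonconstant_trace_is_flagged_degenerate(self):
        dff = np.zeros(40)
        dff[15:18] = 0.01
        call = ca.classify_responder(make_dff(dff, labels(), s=0.0))
        assert call.cls == "OFF" and call.degenerate_baseline

    def test_classification_monotone_in_amplitude(self):
        rng = np.random.default_rng(4)
        noise = rng.normal(0, 0.02, size=40)
        was_responder = False
        for amp in (0.0, 0.05, 0.1, 0.5, 1.0, 2.0):
            dff = noise.copy()
            dff[15:25] += amp
            call = ca.classify_responder(make_dff(dff, labels(), s=0.02))
            if was_responder:
                assert call.cls == "OFF"
            was_responder = was_responder or call.cls == "OFF"
        assert was_responder

    def test_run_detector_matches_dp_oracle(self):
        # P(some run of >= 3 successes in n Bernoulli(p) trials) by DP
        def run_prob(n, p, r=3):
            # state: current trailing-run length (capped at r = absorbed)
            probs = {0: 1.0}
            hit = 0.0
            for _ in range(n):
                nxt = {}
                for run, q in probs.items():
                    succ = q * p
                    if run + 1 >= r:
                        hit += succ
                    else:
                        nxt[run + 1] = nxt.get(run + 1, 0.0) + succ
                    nxt[0] = nxt.get(0, 0.0) + q * (1 - p)
                probs = nxt
            return hit

        rng = np.random.default_rng(8)
        n, p, reps = 12, 0.35, 40000
        masks = rng.random((reps, n)) < p
        detected = np.fromiter(
            (ca.find_first_run(m, 3) >= 0 for m in masks), dtype=bool, count=reps
        )
        assert detected.mean() == pytest.approx(run_prob(n, p), abs=0.01)


class TestResponseTiming:
    def test_linear_decay_crosses_half_max_at_expected_time(self):
        lab = labels(5, 40)
        dff = np.zeros(45)
        ramp_up = np.linspace(0.0, 1.0, 11)       # stimulus frame 5 -> peak at 15
        ramp_down = np.linspace(1.0, 0.0, 21)[1:]  # back to 0 at frame 35
        dff[5:16] = ramp_up
        dff[16:36] = ramp_down
        call = ca.ResponderCall("n", "OFF", onset_frame=7)
        call = ca.response_timing(make_dff(dff, lab), call, stimulus_frame=5)
        assert call.peak_dff == pytest.approx(1.0)
        assert call.time_to_half_max_s == pytest.approx(20.0)
        assert call.returned_within_30s

    def test_monotone_rise_never_returns(self):
        lab = labels(5, 35)
        dff = np.linspace(0.0, 1.0, 40)
        call = ca.ResponderCall("n", "OFF", onset_frame=6)
        call = ca.response_timing(make_dff(dff, lab), call, stimulus_frame=5)
        assert math.isnan(call.time_to_half_max_s)
        assert not call.returned_within_30s

    def test_timing_for_nonresponder_rejected(self):
        call = ca.ResponderCall("n", "none")
        with pytest.raises(ValueError):
            ca.response_timing(make_dff(np.zeros(40), labels()), call)

    def test_planted_kernel_half_max_matches_closed_form(self):
        cfg = synthetic.TraceConfig(n_neurons=2, frac_off=0.5, noise_sd=0.0, seed=0)
        traces, epochs, truth = synthetic.generate_calcium_cohort(cfg)
        calls = ca.classify_cohort(traces, epochs, frame_rate_hz=cfg.frame_rate_hz)
        off = calls[calls["class"] == "OFF"].iloc[0]
        dt = 1.0 / cfg.frame_rate_hz
        expected = (cfg.rise_frames - 1) * dt + cfg.decay_tau_s * math.log(2)
        assert off["time_to_half_max_s"] == pytest.approx(expected, abs=dt)


class TestCohortLevel:
    def test_zero_noise_recovery_is_exact(self):
        cfg = synthetic.TraceConfig(
            n_neurons=20, frac_off=0.25, frac_on=0.15, noise_sd=0.0,
            epoch_plan=(("light", 60.0), ("dark", 60.0), ("light", 60.0)), seed=1,
        )
        traces, epochs, truth = synthetic.generate_calcium_cohort(cfg)
        calls = ca.classify_cohort(traces, epochs)
        merged = calls.merge(truth, on="neuron_id")
        assert (merged["class"] == merged["true_class"]).all()
        resp = merged[merged["true_class"] != "none"]
        assert (resp["onset_frame_x"] - resp["onset_frame_y"]).abs().max() <= 1

    def test_default_noise_recovery(self, calcium_cohort):
        (traces, epochs, truth), _ = calcium_cohort
        calls = ca.classify_cohort(traces, epochs)
        merged = calls.merge(truth, on="neuron_id")
        truth_resp = merged["true_class"].isin(("OFF", "ON"))
        called_resp = merged["class"].isin(("OFF", "ON"))
        sens = (truth_resp & called_resp).sum() / truth_resp.sum()
        spec = (~truth_resp & ~called_resp).sum() / (~truth_resp).sum()
        assert sens >= 0.95 and spec >= 0.95

    def test_summary_fractions(self):
        calls = (
            [ca.ResponderCall(i, "OFF", returned_within_30s=i < 2,
                              time_to_half_max_s=20.0 if i < 2 else 40.0)
             for i in range(3)]
            + [ca.ResponderCall(3, "ON")]
            + [ca.ResponderCall(i, "none") for i in range(4, 10)]
        )
        summary = ca.cohort_response_summary(calls)
        assert summary["pct_off"] == 30.0
        assert summary["frac_on"] == pytest.approx(0.1)
        assert summary["frac_off_returned_30s"] == pytest.approx(2 / 3)

    def test_no_responders_summary_is_all_zero(self):
        summary = ca.cohort_response_summary([ca.ResponderCall(0, "none")])
        assert summary["frac_off"] == 0.0 and summary["frac_on"] == 0.0
        assert summary["frac_off_returned_30s"] == 0.0

    def test_rounding_convention_half_up(self):
        calls = [ca.ResponderCall(i, "OFF") for i in range(46)] + [
            ca.ResponderCall(i, "none") for i in range(46, 299)
        ]
        summary = ca.cohort_response_summary(calls)
        assert summary["pct_off"] == 15.4  # 46/299 = 15.38...%
        assert summary["n_off"] == 46 and summary["n_neurons"] == 299

    def test_frame_epoch_mismatch_rejected(self, calcium_cohort):
        (traces, epochs, _), _ = calcium_cohort
        with pytest.raises(ValueError, match="align"):
            ca.classify_cohort(traces, epochs[epochs["frame"] < 100])
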