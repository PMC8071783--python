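import numpy as np
import pytest
from scipy import integrate

from flowdissect import FlowWaveform, HRFParams, design_response, fit_hrf, \
    hrf_eval, quantify_response


def test_curve_is_zero_at_onset():
    params = HRFParams(A=3.0, c=0.6, alpha1=6.0, alpha2=12.0, beta1=0.9, beta2=0.9)
    assert hrf_eval(params, np.array([0.0]))[0] == 0.0


def test_alpha_at_most_one_rejected():
    with pytest.raises(ValueError):
        HRFParams(A=1.0, c=0.0, alpha1=1.0, alpha2=12.0, beta1=1.0, beta2=1.0)


def test_single_gamma_integrates_to_amplitude():
    # with c = 0 the curve is A times a gamma density
    params = HRFParams(A=2.5, c=0.0, alpha1=6.0, alpha2=12.0, beta1=0.8, beta2=1.0)
    total, _err = integrate.quad(lambda t: hrf_eval(params, np.array([t]))[0],
                                 0, np.inf)
    assert total == pytest.approx(2.5, abs=1e-6)


def test_single_gamma_peak_closed_form():
    # alpha=2, beta=1: t*exp(-t) peaks at t=1 with value 1/e
    params = HRFParams(A=1.0, c=0.0, alpha1=2.0, alpha2=12.0, beta1=1.0, beta2=1.0)
    t = np.arange(0.0, 10.0, 1e-4)
    y = hrf_eval(params, t)
    assert t[np.argmax(y)] == pytest.approx(1.0, abs=2e-4)
    assert y.max() == pytest.approx(np.exp(-1.0), abs=1e-8)


@pytest.mark.parametrize("peak,under", [
    (2.19, 0.86), (0.92, 1.96), (3.37, 3.04), (1.30, 0.0),
])
def test_design_response_attains_requested_features(peak, under):
    resp = design_response(peak, under, peak_time=7.3, undershoot_time=15.0)
    t = np.arange(0.0, 30.0, 1e-3)
    y = resp.curve(t) * 100.0
    assert y.max() == pytest.approx(peak, rel=1e-6)
    assert t[np.argmax(y)] == pytest.approx(7.3, abs=0.01)
    assert resp.peak_fraction == pytest.approx(peak / 100.0)
    if under > 0:
        assert -y.min() == pytest.approx(under, rel=1e-4)
        assert t[np.argmin(y)] == pytest.approx(15.0, abs=0.01)
    else:
        assert y.min() >= 0.0


def _waveform_from(resp, protocol, noise_sd=0.0, rng=None):
    t = protocol.frame_times
    values = 1.0 + resp.curve(t - protocol.stim_onset)
    if noise_sd:
        values = values + noise_sd * rng.standard_normal(t.size)
    return FlowWaveform(times=t, values=values,
                        baseline_window=protocol.baseline_window,
                        stim_window=protocol.stim_window)


def test_fit_recovers_noise_free_parameters(protocol, small_peak_response):
    w = _waveform_from(small_peak_response, protocol)
    fit = fit_hrf(w)
    assert fit.accepted
    assert fit.r_squared > 0.999
    true = small_peak_response
    # fit works in percent: A is 100x the fractional-unit truth
    assert fit.params.A == pytest.approx(100.0 * true.A_true, rel=1e-3)
    assert fit.params.c == pytest.approx(true.c_true, rel=1e-3)
    assert fit.params.alpha1 == pytest.approx(true.alpha1_true, rel=1e-3)
    assert fit.params.beta1 == pytest.approx(true.beta1_true, rel=1e-3)


def test_pure_noise_fails_r2_gate(protocol):
    rng = np.random.default_rng(0)
    t = protocol.frame_times
    w = FlowWaveform(times=t, values=1.0 + 0.01 * rng.standard_normal(t.size),
                     baseline_window=protocol.baseline_window,
                     stim_window=protocol.stim_window)
    fit = fit_hrf(w)
    assert not fit.accepted


def test_fit_needs_enough_post_onset_samples(protocol, small_peak_response):
    w = _waveform_from(small_peak_response, protocol)
    short = FlowWaveform(times=w.times[:14], values=w.values[:14],
                         baseline_window=w.baseline_window,
                         stim_window=w.stim_window)
    with pytest.raises(ValueError, match="post-onset"):
        fit_hrf(short)


def test_quantify_no_undershoot_when_curve_nonnegative(protocol):
    resp = design_response(2.0, 0.0)
    w = _waveform_from(resp, protocol)
    fit = fit_hrf(w)
    m = quantify_response(fit)
    assert m.undershoot_amplitude is None
    assert m.undershoot_time is None
    assert m.negative_interval is None
    assert m.integral_negative == 0.0
    assert m.integral_positive > 0


def test_quantify_matches_finer_grid_oracle(protocol, small_peak_response):
    w = _waveform_from(small_peak_response, protocol)
    fit = fit_hrf(w)
    m1 = quantify_response(fit, dt=1e-3)
    m0 = quantify_response(fit, dt=1e-4)   # brute-force finer grid
    assert m1.peak_amplitude == pytest.approx(m0.peak_amplitude, abs=1e-4)
    assert m1.peak_time == pytest.approx(m0.peak_time, abs=2e-3)
    assert m1.undershoot_amplitude == pytest.approx(m0.undershoot_amplitude,
                                                    abs=1e-4)
    assert m1.integral_positive == pytest.approx(m0.integral_positive, abs=1e-3)
    assert m1.integral_negative == pytest.approx(m0.integral_negative, abs=1e-3)
    assert m1.peak_time < m1.undershoot_time
    assert m1.integral_positive >= 0 >= m1.integral_negative


def test_amplitude_recovery_under_noise(protocol, small_peak_response):
    """Median |peak error| stays below the injected noise SD (20% of peak)."""
    rng = np.random.default_rng(123)
    truth = 2.19
    noise_sd_pct = 0.2 * truth
    errors = []
    for _ in range(40):
        w = _waveform_from(small_peak_response, protocol,
                           noise_sd=noise_sd_pct / 100.0, rng=rng)
        fit = fit_hrf(w)
        m = quantify_response(fit)
        errors.append(m.peak_amplitude - truth)
    errors = np.array(errors)
    assert np.median(np.abs(errors)) < noise_sd_pct
    assert abs(errors.mean()) < 0.1 * truth
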