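import numpy as np
import pytest

from flowdissect import G2FitError, VesselSpec, compute_angiogram, \
    diameter_class, extract_flow_index, simulate_bscan_series, simulate_g2, \
    simulate_dcs_waveform, simulate_trial, trial_flow_truth
from flowdissect.hrf import design_response

from conftest import flat_response, three_vessel_scene


def test_diameter_binning_rule():
    assert diameter_class(8.0) == "small"
    assert diameter_class(10.0) == "medium"   # closed medium interval
    assert diameter_class(20.0) == "medium"
    assert diameter_class(28.0) == "large"


def test_vessel_class_truth_must_match_diameter():
    with pytest.raises(ValueError, match="inconsistent"):
        VesselSpec(center_um=(50.0, 50.0), diameter_um=8.0,
                   baseline_decorrelation=0.5, response=flat_response(),
                   class_truth="large")


def test_overlapping_vessels_rejected():
    scene = three_vessel_scene()
    v = scene.vessels
    with pytest.raises(ValueError, match="overlap"):
        type(scene)(shape_px=scene.shape_px, vessels=[v[0], v[0]])


def test_static_scene_has_identical_repeats():
    scene = three_vessel_scene(detector_noise_sd=0.0)
    rng = np.random.default_rng(0)
    series = simulate_bscan_series(scene, np.zeros(3), repeats=6, rng=rng)
    assert np.array_equal(series.data[0], series.data[3])
    assert np.all(compute_angiogram(series).values == 0.0)


def test_same_seed_gives_bit_identical_output():
    scene = three_vessel_scene()
    a = simulate_bscan_series(scene, np.ones(3), 8, np.random.default_rng(42))
    b = simulate_bscan_series(scene, np.ones(3), 8, np.random.default_rng(42))
    assert np.array_equal(a.data, b.data)


def test_unknown_vessel_key_and_negative_flow_rejected():
    scene = three_vessel_scene()
    rng = np.random.default_rng(0)
    with pytest.raises(KeyError):
        simulate_bscan_series(scene, {9: 1.0}, 4, rng)
    with pytest.raises(ValueError):
        simulate_bscan_series(scene, np.array([1.0, -1.0, 1.0]), 4, rng)


def test_contrast_monotone_in_flow_inside_vessel_only():
    """Doubling one vessel's flow raises angiogram contrast only there."""
    scene = three_vessel_scene()
    ii, jj, cov = scene.coverage()[2]          # the 28-um vessel
    core = cov > 0.99
    a1 = compute_angiogram(simulate_bscan_series(
        scene, np.array([1.0, 1.0, 1.0]), 1000, np.random.default_rng(5))).values
    a2 = compute_angiogram(simulate_bscan_series(
        scene, np.array([1.0, 1.0, 2.0]), 1000, np.random.default_rng(5))).values
    assert a2[ii[core], jj[core]].mean() > 1.5 * a1[ii[core], jj[core]].mean()
    outside = np.ones(scene.shape_px, dtype=bool)
    outside[ii, jj] = False
    assert np.array_equal(a1[outside], a2[outside])


def test_trial_returns_protocol_frame_count(protocol):
    scene = three_vessel_scene()
    series, truth = simulate_trial(protocol, scene, np.random.default_rng(1))
    assert len(series) == 65
    assert all(t.shape == (65,) for t in truth.values())


def test_null_response_gives_constant_unit_flow(protocol):
    scene = three_vessel_scene()          # all responses flat
    truth = trial_flow_truth(protocol, scene)
    for course in truth.values():
        assert np.allclose(course, 1.0)


def test_truth_course_peaks_at_design_latency(protocol):
    resp = design_response(5.0, 2.0, peak_time=7.3)
    scene = three_vessel_scene(responses={"large": resp})
    truth = trial_flow_truth(protocol, scene)[2]
    t_dense = np.arange(0.0, 25.0, 1e-3)
    t_star = t_dense[np.argmax(resp.curve(t_dense))] + protocol.stim_onset
    t_frame = protocol.frame_times[np.argmax(truth)]
    assert abs(t_frame - t_star) <= protocol.composite_frame_period / 2 + 1e-9


def test_dcs_waveform_sampling_and_amplitude(protocol):
    rng = np.random.default_rng(0)
    flat = flat_response()
    w0 = simulate_dcs_waveform(protocol, flat, 0.0, rng)
    assert w0.times.size == 132
    assert np.all(w0.values == 1.0)

    resp = design_response(3.37, 3.04)
    w = simulate_dcs_waveform(protocol, resp, 0.0, rng)
    assert w.values.max() == pytest.approx(1.0 + resp.peak_fraction, abs=5e-4)
    assert w.values.max() <= 1.0 + resp.peak_fraction + 1e-12


def test_g2_limits_and_roundtrip():
    tau = np.geomspace(1e-7, 1e-2, 64)
    g2 = simulate_g2(2.5, beta=0.5, tau_grid=tau)
    assert simulate_g2(2.5, 0.5, np.array([0.0]))[0] == pytest.approx(1.5)
    assert g2[-1] == pytest.approx(1.0, abs=1e-6)
    assert extract_flow_index(g2, tau) == pytest.approx(2.5, abs=1e-6)


def test_g2_non_decaying_curve_flagged():
    tau = np.linspace(0.0, 1e-3, 32)
    rising = 1.0 + 0.5 * tau / tau.max()
    with pytest.raises(G2FitError):
        extract_flow_index(rising, tau)
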