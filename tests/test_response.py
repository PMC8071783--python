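import dataclasses

import numpy as np
import pytest

from flowdissect import FlowWaveform, WaveformSource, average_presentations, \
    compute_angiogram, extract_class_response, normalize_to_baseline, \
    resample_to_grid, segment_vessels, simulate_trial
from flowdissect.angiography import AngiogramFrame
from flowdissect.hrf import design_response

from conftest import multi_vessel_scene


def _wave(values, times=None, baseline=(0.0, 3.0)):
    values = np.asarray(values, dtype=float)
    times = np.arange(values.size, dtype=float) if times is None else times
    return FlowWaveform(times=times, values=values, baseline_window=baseline,
                        stim_window=(5.0, 9.0))


def test_normalize_constant_series_to_ones():
    w = normalize_to_baseline(_wave([4.0, 4.0, 4.0, 4.0]))
    assert np.allclose(w.values, 1.0)


def test_normalize_hand_example():
    # [2,2,2,4] with baseline over the first three samples -> [1,1,1,2]
    w = normalize_to_baseline(_wave([2.0, 2.0, 2.0, 4.0]))
    assert np.allclose(w.values, [1.0, 1.0, 1.0, 2.0])


def test_normalize_rejects_nonpositive_baseline():
    with pytest.raises(ValueError):
        normalize_to_baseline(_wave([0.0, 0.0, 0.0, 1.0]))


def test_normalize_is_idempotent():
    rng = np.random.default_rng(0)
    w = normalize_to_baseline(_wave(rng.uniform(1.0, 2.0, 20)))
    again = normalize_to_baseline(w)
    assert np.allclose(again.values, w.values)
    assert abs(np.mean(w.values[w.baseline_mask()]) - 1.0) < 1e-9


def test_average_identical_waveforms_counts_presentations():
    w = _wave([1.0, 1.1, 0.9, 1.0])
    avg = average_presentations([w] * 10)
    assert np.allclose(avg.values, w.values)
    assert avg.n_averaged == 10


def test_average_two_waveforms_pointwise():
    avg = average_presentations([_wave([1.0, 2.0]), _wave([1.0, 0.0])])
    assert np.allclose(avg.values, [1.0, 1.0])


def test_average_rejects_grid_mismatch():
    a = _wave([1.0, 2.0, 3.0])
    b = _wave([1.0, 2.0, 3.0], times=np.array([0.0, 1.5, 3.0]))
    with pytest.raises(ValueError, match="grid"):
        average_presentations([a, b])


def test_sem_shrinks_as_sqrt_n():
    """SD of the presentation mean scales as 1/sqrt(n)."""
    rng = np.random.default_rng(42)
    sds = {}
    for n in (1, 4, 16):
        means = []
        for _ in range(300):
            waves = [_wave(1.0 + 0.2 * rng.standard_normal(8))
                     for _ in range(n)]
            means.append(average_presentations(waves).values[0]
                         if n > 1 else waves[0].values[0])
        sds[n] = np.std(means)
    assert sds[4] == pytest.approx(sds[1] / 2.0, rel=0.25)
    assert sds[16] == pytest.approx(sds[1] / 4.0, rel=0.25)


def test_resample_identity_and_linearity():
    t = np.linspace(0.0, 10.0, 21)
    w = _wave(2.0 + 0.3 * t, times=t)
    same = resample_to_grid(w, t)
    assert np.allclose(same.values, w.values)
    fine = resample_to_grid(w, np.linspace(0.5, 9.5, 37))
    assert np.allclose(fine.values, 2.0 + 0.3 * fine.times)  # exact on a ramp


def test_resample_dcs_grid_onto_frame_centers(protocol):
    t_dcs = protocol.dcs_times
    w = _wave(np.ones(t_dcs.size), times=t_dcs)
    out = resample_to_grid(w, protocol.frame_times)
    assert out.times.size == 65


def test_resample_refuses_extrapolation():
    w = _wave([1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="span"):
        resample_to_grid(w, np.array([-1.0, 0.5]))


def _class_waveforms(protocol, scene, n_presentations, seed):
    root = np.random.SeedSequence(seed)
    per_class = {}
    masks = None
    stacks = []
    for child in root.spawn(n_presentations):
        rng = np.random.default_rng(child)
        series, _ = simulate_trial(protocol, scene, rng)
        stacks.append(np.stack([compute_angiogram(s).values for s in series]))
    baseline = np.mean([s[:protocol.n_baseline_frames].mean(axis=0)
                        for s in stacks], axis=0)
    masks = segment_vessels(AngiogramFrame(values=baseline,
                                           pixel_size_um=scene.pixel_size_um))
    for stack in stacks:
        for cls, w in extract_class_response(stack, masks, protocol).items():
            per_class.setdefault(cls, []).append(w)
    return {cls: average_presentations(ws) for cls, ws in per_class.items()}, masks


def test_null_trial_waveforms_stay_at_unity(protocol):
    scene = multi_vessel_scene()               # all responses flat
    waves, _ = _class_waveforms(protocol, scene, n_presentations=6, seed=21)
    for cls, w in waves.items():
        assert w.times.size == 65
        tol = 6.0 * np.nanmax(w.sem)
        assert np.max(np.abs(w.values - 1.0)) < tol


def test_response_only_in_large_vessels_stays_in_large_class(protocol):
    """A response confined to large vessels must not leak into the other
    class waveforms.  Comparing against a null run with identical seeds
    cancels the shared speckle noise, isolating any leakage."""
    resp = design_response(15.0, 5.0)          # strong, unambiguous response
    with_resp, _ = _class_waveforms(
        protocol, multi_vessel_scene(responses={"large": resp}, seed=13),
        n_presentations=6, seed=22)
    null, _ = _class_waveforms(
        protocol, multi_vessel_scene(seed=13), n_presentations=6, seed=22)

    def window_dev(w):
        sel = (w.times >= 10.0) & (w.times <= 14.5)   # around the peak
        return float(np.mean(w.values[sel]) - 1.0)

    assert window_dev(with_resp["large"]) - window_dev(null["large"]) > 0.10
    for cls in ("small", "medium"):
        leak = abs(window_dev(with_resp[cls]) - window_dev(null[cls]))
        assert leak < 0.01                      # < ~8% of the large response


def test_extraction_commutes_with_global_gain(protocol):
    scene = multi_vessel_scene()
    rng = np.random.default_rng(3)
    series, _ = simulate_trial(protocol, scene, rng)
    stack = np.stack([compute_angiogram(s).values for s in series])
    masks = segment_vessels(AngiogramFrame(
        values=stack[:protocol.n_baseline_frames].mean(axis=0),
        pixel_size_um=scene.pixel_size_um))
    w1 = extract_class_response(stack, masks, protocol)
    w2 = extract_class_response(stack * 3.7, masks, protocol)
    for cls in w1:
        assert np.allclose(w1[cls].values, w2[cls].values)
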