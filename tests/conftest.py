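import numpy as np
import pytest

from flowdissect import GroundTruthResponse, SceneConfig, VesselSpec, \
    design_response, make_protocol


@pytest.fixture(scope="session")
def protocol():
    return make_protocol()


def flat_response() -> GroundTruthResponse:
    """A null (zero-amplitude) ground-truth response."""
    return GroundTruthResponse(A_true=0.0, c_true=0.0, alpha1_true=2.0,
                               alpha2_true=3.0, beta1_true=1.0, beta2_true=1.0,
                               peak_fraction=0.0)


@pytest.fixture(scope="session")
def small_peak_response():
    return design_response(2.19, 0.86)


def three_vessel_scene(responses=None, detector_noise_sd=0.05,
                       parenchyma_noise_sd=0.3, seed=7) -> SceneConfig:
    """Tiny scene with one vessel of each diameter class (8/16/28 um)."""
    responses = responses or {}
    flat = flat_response()
    vessels = [
        VesselSpec(center_um=(100.0, 60.0), diameter_um=8.0,
                   baseline_decorrelation=0.45,
                   response=responses.get("small", flat)),
        VesselSpec(center_um=(120.0, 160.0), diameter_um=16.0,
                   baseline_decorrelation=0.9,
                   response=responses.get("medium", flat)),
        VesselSpec(center_um=(80.0, 260.0), diameter_um=28.0,
                   baseline_decorrelation=0.9,
                   response=responses.get("large", flat)),
    ]
    return SceneConfig(shape_px=(60, 80), pixel_size_um=(4.0, 4.0),
                       vessels=vessels, detector_noise_sd=detector_noise_sd,
                       parenchyma_noise_sd=parenchyma_noise_sd, rng_seed=seed)


def multi_vessel_scene(responses=None, seed=11) -> SceneConfig:
    """Mid-size scene with several vessels per class (for waveform tests)."""
    responses = responses or {}
    flat = flat_response()
    vessels = []
    for k, (cz, cx) in enumerate([(60, 40), (120, 90), (180, 140), (240, 200),
                                  (60, 250), (200, 300), (120, 380), (260, 430)]):
        vessels.append(VesselSpec(
            center_um=(float(cz), float(cx)), diameter_um=8.0,
            baseline_decorrelation=0.45, response=responses.get("small", flat)))
    for cz, cx in [(160, 240), (280, 80)]:
        vessels.append(VesselSpec(
            center_um=(float(cz), float(cx)), diameter_um=16.0,
            baseline_decorrelation=0.9, response=responses.get("medium", flat)))
    for cz, cx in [(60, 140), (240, 340)]:
        vessels.append(VesselSpec(
            center_um=(float(cz), float(cx)), diameter_um=28.0,
            baseline_decorrelation=0.9, response=responses.get("large", flat)))
    return SceneConfig(shape_px=(80, 120), pixel_size_um=(4.0, 4.0),
                       vessels=vessels, rng_seed=seed)
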