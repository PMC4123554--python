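import numpy as np
import pytest

from vertelab import phantom, pipeline, profile


@pytest.fixture(scope="session")
def default_template():
    return phantom.default_phantom_template()


@pytest.fixture(scope="session")
def clean_phantom():
    """Moderate-noise curved t2-like phantom with its ground truth."""
    cfg = phantom.PhantomConfig(seed=7)
    volume, truth = phantom.generate_phantom(cfg)
    return cfg, volume, truth


@pytest.fixture(scope="session")
def straight_phantom():
    """Noiseless, bias-free, straight phantom for geometry-sensitive tests."""
    cfg = phantom.PhantomConfig(
        seed=3, noise_sd=0.0, bias_field_amplitude=0.0, curvature_amplitude_mm=0.0
    )
    volume, truth = phantom.generate_phantom(cfg)
    return cfg, volume, truth


@pytest.fixture(scope="session")
def clean_profile(clean_phantom, default_template):
    """Fully prepared (detrended, normalized, peak-normalized) spine profile."""
    from vertelab import detection

    _, volume, truth = clean_phantom
    cl = profile.centerline_from_mask(truth.cord_mask)
    prof = profile.sample_profile(volume, profile.shift_centerline_anterior(cl))
    prof = profile.detrend_profile(prof)
    prof = profile.normalize_profile(prof)
    return detection.normalize_peaks(
        prof, min_separation_mm=0.5 * default_template.min_gap_mm
    )


def run_full_pipeline(volume, truth, template, **config_kwargs):
    """Label one phantom volume against its own cord mask."""
    contrast = "t1" if volume.polarity == "t1_like" else "t2"
    config = pipeline.PipelineConfig(contrast=contrast, **config_kwargs)
    cl = profile.centerline_from_mask(truth.cord_mask)
    return pipeline.label_volume(volume, cl, template, config)
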