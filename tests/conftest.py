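import numpy as np
import pytest
from hypothesis import settings

from vesselcaliber.centerline import extract_centerline_segments
from vesselcaliber.config import PipelineConfig
from vesselcaliber.geometry import fit_spline
from vesselcaliber.pipeline import collect_validation_records
from vesselcaliber.profiles import (
    StraightenedSegment,
    determine_limits,
    initial_half_length,
    sample_profile,
    smoothed_mean_profile,
)
from vesselcaliber.synthetic import (
    SyntheticVesselSpec,
    make_validation_specs,
    render_vessel_image,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def straight_vessel_dataset():
    """Noiseless straight vessel of diameter 10 with exact ground truth."""
    spec = SyntheticVesselSpec(
        diameter=10.0, curve="line", p0=(20, 60), p1=(140, 80), noise_sd=0.0
    )
    return render_vessel_image([spec], shape=(160, 160), seed=0)


@pytest.fixture
def vessel_profile_limits():
    """Factory: per-profile extent decisions for one rendered vessel."""

    def _run(diameter, clr_depth=0.0, n_profiles=10, seed=0, curve="line"):
        spec = SyntheticVesselSpec(
            diameter=diameter,
            curve=curve,
            p0=(20, 60),
            p1=(140, 85),
            noise_sd=0.0,
            clr_depth=clr_depth,
        )
        ds = render_vessel_image([spec], shape=(160, 160), seed=seed)
        segment = max(extract_centerline_segments(ds.mask), key=len)
        half = initial_half_length(ds.mask)
        smoothed = fit_spline(segment)
        rows = [
            sample_profile(ds.image[:, :, 1], p, n, half)
            for p, n in zip(smoothed.samples, smoothed.normals)
        ]
        straight = StraightenedSegment(rows=rows)
        n = len(rows)
        margin = max(1, n // 10)
        idx = np.linspace(margin, n - 1 - margin, n_profiles).astype(int)
        return [
            determine_limits(
                smoothed_mean_profile(straight, r), initial_half_len=half
            )
            for r in idx
        ]

    return _run


@pytest.fixture(scope="session")
def validation_records():
    """Matched parameter/width records for the synthetic width-recovery
    study: 32 vessels, diameters 4-20 px, noise sd 0.02, DoG-L7 model.

    Session-scoped: the cross-validation and leave-one-segment-out checks
    share this computation.
    """
    specs = make_validation_specs(n_vessels=32, seed=11)
    config = PipelineConfig(model_id="dogl7", profile_step=3, seed=11)
    return collect_validation_records(specs, config, shape=(160, 160), seed=100)
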