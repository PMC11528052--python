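import numpy as np
import pytest

from pactrack import kinetics as K
from pactrack import phantom
from pactrack.saft import ScanGeometry


@pytest.fixture
def geometry():
    """Elevational-scan geometry: 20 mm focus, 8 mm element, 0.1 mm step."""
    return ScanGeometry(
        lf_mm=20.0, w_mm=8.0, dz_mm=0.1, fs_hz=40e6, c_mm_per_us=1.5,
        n0=20.0 / 1.5 * 40.0,
    )


@pytest.fixture
def truth_params():
    return K.EMMParams(a=80.0, t0=5.0, alpha=0.05, beta=0.002, q=1.5, f_ratio=1.0)


@pytest.fixture
def clean_curve(truth_params):
    t = np.arange(0.0, 601.0, 1.0)
    y = K.emm_evaluate(truth_params, t)
    return K.ROITimeCourse(times=t, values=y, kind="relative-enhancement")


@pytest.fixture
def point_stack(geometry):
    """Three defocused targets 5-10 mm beyond focus, mild seeded noise."""
    targets = tuple(
        phantom.PointTarget(depth_mm=20.0 + d, elevation_mm=e)
        for d, e in [(5.0, 4.0), (7.5, 8.0), (10.0, 12.0)]
    )
    scene = phantom.PointTargetScene(targets=targets, noise_sigma=0.01, seed=1)
    stack, truth = phantom.make_point_target_stack(
        scene, geometry, n_scans=161, n_samples=1024
    )
    return stack, truth
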