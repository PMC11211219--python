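import numpy as np
import pytest

from aolvratio.cohort import CohortConfig, generate_cohort
from aolvratio.phantom import PhantomSpec


def make_small_phantom_spec(spacing: float = 1.46, **overrides) -> PhantomSpec:
    """A compact 3-chamber phantom (~188 mm field of view) for fast tests.

    Landmark coordinates are deliberately off the pixel grid so the 1 cm^2
    ROI discretises accurately at every tested spacing.
    """
    shape = int(np.ceil(188.0 / spacing))
    defaults = dict(
        image_shape=(shape, shape),
        pixel_spacing=(spacing, spacing),
        n_frames=12,
        end_systolic_frame=4,
        lv_center=(120.7, 80.3),
        lv_semi_axes_diastole=(30.0, 20.0),
        lv_contraction_fraction=0.35,
        myocardial_thickness=7.0,
        valve_point=(70.4, 95.3),
        aorta_direction=(-1.0, 0.0),
        aorta_diameter=24.0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_spec():
    return make_small_phantom_spec()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-preset cohort (seed 0), shared across read-only tests."""
    return generate_cohort(CohortConfig.default(seed=0))
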