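import numpy as np
import pytest

from spectrohist import PhantomParams, default_class_models, make_cohort
from spectrohist.metrics import default_region_table
from spectrohist.phantom import make_phantom


#: compact phantom settings used by most tests; small frame + coarse axis
#: keep the suite fast while exercising every pipeline stage
def small_params(**overrides) -> PhantomParams:
    defaults = dict(image_size=(32, 32), axis_spacing=8.0, seed=0)
    defaults.update(overrides)
    return PhantomParams(**defaults)


@pytest.fixture(scope="session")
def region_table():
    return default_region_table()


@pytest.fixture(scope="session")
def small_cohort():
    """Six mice, compact frames: enough for LOMO plumbing tests."""
    return make_cohort(
        n_mice=6,
        genotype_mix={"control": 2, "KC": 2, "KPC": 2},
        params=small_params(),
        seed=11,
    )


@pytest.fixture(scope="session")
def kpc_phantom():
    """One all-seven-classes phantom with its clean reference."""
    params = small_params(
        axis_spacing=4.0,  # default-table regions need the full grid density
        class_fractions={
            "benign": 0.25, "cancer": 0.12, "PanIN": 0.08, "inflammation": 0.05,
            "fiber": 0.08, "blood": 0.04, "necrosis": 0.04,
        },
        seed=5,
    )
    rng = np.random.default_rng(5)
    return make_phantom(params, default_class_models(), "kpc01", "KPC", rng)
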