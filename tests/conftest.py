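import numpy as np
import pytest
from hypothesis import settings

from kneejsw.phantom import PhantomSpec, make_phantom

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def plate_spec(thickness=1.0, gap=0.5, **kwargs):
    """Parallel-plate phantom spec: flat surfaces, uniform cartilage."""
    kwargs.setdefault("condyle_radius", 0.0)
    kwargs.setdefault("plateau_tilt_deg", 0.0)
    return PhantomSpec(
        cartilage_tibial={"medial": thickness, "lateral": thickness},
        cartilage_femoral={"medial": thickness, "lateral": thickness},
        residual_gap=gap,
        **kwargs,
    )


@pytest.fixture
def plates_4mm():
    """Parallel plates with a 4.0 mm bone-to-bone gap."""
    return make_phantom(plate_spec(thickness=1.75, gap=0.5))


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
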