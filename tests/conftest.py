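import numpy as np
import pytest

from pelviflow import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default synthetic subject: 30 frames, 15 mm descent, 10 deg tilt."""
    return make_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def textured_image():
    """A smooth random field with plenty of gradient structure everywhere."""
    from scipy import ndimage as ndi

    rng = np.random.default_rng(7)
    img = ndi.gaussian_filter(rng.standard_normal((128, 128)), 2.0)
    img -= img.min()
    return img / img.max()
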