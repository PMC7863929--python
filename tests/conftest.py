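import numpy as np
import pytest

from hscurve import (
    ClassLabel,
    HSICube,
    PhantomSpec,
    calibrate,
    make_cube,
    make_profile,
    normalize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_cube(rng):
    """A 12x12x6 normalized cube with generic structure, for I/O and window tests."""
    data = rng.uniform(0.0, 1.0, (12, 12, 6))
    data.flat[0], data.flat[1] = 0.0, 1.0  # pin the range
    return HSICube(data=data, wavelengths=np.linspace(450, 950, 6), id="small", provenance="normalized")


@pytest.fixture(scope="session")
def melanoma_capture():
    """One full-size melanoma phantom: (raw, refs, truth label)."""
    profile = make_profile(ClassLabel.MELANOMA, rng=101)
    return make_cube(profile, PhantomSpec(seed=202))


@pytest.fixture(scope="session")
def norm_cube(melanoma_capture):
    """The melanoma phantom calibrated and normalized (full-size 50x50x125)."""
    raw, refs, _ = melanoma_capture
    return normalize(calibrate(raw, refs))
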