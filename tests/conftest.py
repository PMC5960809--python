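"""Shared fixtures: small, fast phantom geometries for unit tests.

The "tiny" spec shrinks both the grid and the head so registration-heavy
tests run in seconds; the "fast" spec is the half-resolution (2 mm)
variant of the study geometry used by the acceptance suite.
"""

import numpy as np
import pytest

from ctavg.phantom import PhantomSpec, generate_control
from ctavg.volumes import preprocess


def make_tiny_spec(**overrides) -> PhantomSpec:
    base = dict(
        shape=(30, 40, 40),
        spacing=(3.0, 3.0, 3.0),
        skull_semiaxes=(32.0, 44.0, 40.0),
        skull_thickness=6.0,
        gray_thickness=5.0,
        ventricle_semiaxes=(8.0, 12.0, 6.0),
        ventricle_offset_x=10.0,
        trans_jitter_mm=3.0,
        warp_amp_mm=2.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    return make_tiny_spec()


@pytest.fixture(scope="session")
def tiny_control(tiny_spec):
    """One preprocessed tiny control: (volume, head mask, sidecar)."""
    vol, sidecar = generate_control(tiny_spec, seed=11)
    pre, mask = preprocess(vol, slice_mm=float(vol.spacing[0]))
    return pre, mask, sidecar


@pytest.fixture(scope="session")
def fast_spec() -> PhantomSpec:
    return PhantomSpec().fast()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
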