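"""Shared fixtures: small sensors and fast reduced-resolution phantoms."""

import numpy as np
import pytest

from depthresp import CameraIntrinsics, PhantomConfig


@pytest.fixture
def intr500():
    """640x576 sensor with fx = fy = 500 and centred principal point."""
    return CameraIntrinsics(fx=500.0, fy=500.0, cx=320.0, cy=288.0,
                            width=640, height=576)


@pytest.fixture
def intr_small():
    """Small 64x64 sensor for brute-force geometry oracles."""
    return CameraIntrinsics(fx=80.0, fy=80.0, cx=31.5, cy=31.5,
                            width=64, height=64)


def small_phantom(**overrides) -> PhantomConfig:
    """Adult-scale phantom at reduced resolution for fast tests."""
    params = dict(resolution=(160, 144), duration=12.0, seed=7)
    params.update(overrides)
    return PhantomConfig.adult(**params)


def small_child_phantom(**overrides) -> PhantomConfig:
    params = dict(resolution=(160, 144), duration=12.0, seed=7)
    params.update(overrides)
    return PhantomConfig.child(**params)


@pytest.fixture
def phantom_factory():
    return small_phantom


@pytest.fixture
def child_phantom_factory():
    return small_child_phantom
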