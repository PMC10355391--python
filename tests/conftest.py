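import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from retseg import (PipelineConfig, generate_phantom, run_pipeline,
                    small_phantom_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """One reduced phantom shared by read-only tests."""
    return generate_phantom(small_phantom_spec(seed=1))


@pytest.fixture(scope="session")
def small_run(small_phantom):
    """Default-config pipeline run on the shared small phantom."""
    image, truth, fov, centerlines = small_phantom
    seg, record = run_pipeline(image, fov, PipelineConfig())
    return seg, record


def make_bar(height, width, angle_deg, halfwidth=2.0, depth=0.6, background=0.8):
    """Dark bar through the image center using the detector's rotation
    convention (u = x cos(theta) - y sin(theta); x = col, y = row offsets).

    Returns (image, centerline_mask)."""
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    x = xx - width / 2.0
    y = yy - height / 2.0
    th = np.deg2rad(angle_deg)
    u = x * np.cos(th) - y * np.sin(th)
    img = np.where(np.abs(u) <= halfwidth, background - depth, background)
    return img, np.abs(u) <= 0.5
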