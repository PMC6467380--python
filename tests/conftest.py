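"""Shared fixtures: small fast synthetic datasets plus the full-size tables
used by the end-to-end classification checks (session-scoped so the feature
extraction cost is paid once)."""

import numpy as np
import pytest

from ehgkit import (
    SampEnParams,
    WaveletSpec,
    generate_dataset,
    identical_config,
    separable_config,
)
from ehgkit.features import build_feature_table

SMALL_KW = dict(n_channels=4, n_points=512)


@pytest.fixture(scope="session")
def small_separable_table():
    """4-channel, 512-point, 20+20-segment table: fast classification checks."""
    cfg = separable_config(seed=11, **SMALL_KW)
    segments, _ = generate_dataset(cfg, 20)
    return build_feature_table(segments, WaveletSpec(), SampEnParams())


@pytest.fixture(scope="session")
def full_separable_table():
    """The study conditions: 16 channels, 4096 points, 150 segments per class."""
    cfg = separable_config(seed=42)
    segments, _ = generate_dataset(cfg, 150)
    return build_feature_table(segments, WaveletSpec(), SampEnParams())


@pytest.fixture(scope="session")
def full_control_table():
    """Identical-classes control at full size: labels carry no signal."""
    cfg = identical_config(seed=42)
    segments, _ = generate_dataset(cfg, 150)
    return build_feature_table(segments, WaveletSpec(), SampEnParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
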