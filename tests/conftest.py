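import numpy as np
import pytest

from gkvisc import OuSpec, PressureTensorSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def off_diagonal_series(rng):
    """Small random series with only the three off-diagonal components."""
    n = 64
    return PressureTensorSeries(
        time_step=0.5,
        components={lbl: rng.standard_normal(n) for lbl in ("xy", "xz", "yz")},
        volume=120.0,
        temperature=300.0,
        trajectory_id="offdiag",
    )


@pytest.fixture
def full_tensor_series(rng):
    """Small random series with all nine tensor components."""
    n = 64
    labels = ("xx", "yy", "zz", "xy", "xz", "yz", "yx", "zx", "zy")
    return PressureTensorSeries(
        time_step=0.25,
        components={lbl: rng.standard_normal(n) for lbl in labels},
        volume=80.0,
        temperature=298.0,
        trajectory_id="full",
    )


@pytest.fixture
def two_mode_spec():
    """OU spec with a two-decade timescale spread, small enough for unit tests."""
    return OuSpec(
        modes=[(0.5, 1.0), (0.05, 50.0)],
        time_step=0.1,
        n_steps=50_000,
        volume=100.0,
        temperature=298.0,
        seed=4242,
    )
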