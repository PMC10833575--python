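import numpy as np
import pytest

from fluoroquant.phantom import PhantomSpec, generate_evaluation_dataset

# Scaled-down phantom geometry used throughout the tests: a 34 x 25.5 mm
# field at the native 0.085 mm pitch, large enough for the 5 mm background
# margin to leave tissue on every side of a ~3 mm-radius tumor.
SMALL = dict(width=400, height=300, pixel_size_mm=0.085)


@pytest.fixture(scope="session")
def small_rim_spec() -> PhantomSpec:
    return PhantomSpec(pattern="rim", noise_sd=0.0, seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_filled_spec() -> PhantomSpec:
    return PhantomSpec(pattern="filled", noise_sd=0.0, seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory) -> str:
    """A 3-loaf rim dataset with mild observer jitter and image noise."""
    out = tmp_path_factory.mktemp("dataset")
    base = PhantomSpec(pattern="rim", noise_sd=0.005, **SMALL)
    generate_evaluation_dataset(
        out, n_loaves=3, pattern="rim", jitter_sd_px=2.0, seed=21, base_spec=base
    )
    return str(out)


@pytest.fixture(scope="session")
def perfect_dataset(tmp_path_factory) -> str:
    """A 2-loaf dataset drawn by error-free observers (no jitter, no bias)."""
    out = tmp_path_factory.mktemp("perfect")
    base = PhantomSpec(pattern="rim", noise_sd=0.0, **SMALL)
    generate_evaluation_dataset(
        out, n_loaves=2, pattern="rim", jitter_sd_px=0.0, bias_px=0.0, seed=31, base_spec=base
    )
    return str(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
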