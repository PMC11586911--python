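import numpy as np
import pytest

from gemdiol import surfaces, synthetic, umbrella


@pytest.fixture(scope="session")
def double_well_windows():
    """Small biased dataset on the 2 kcal/mol double well, shared across
    WHAM tests (session-scoped: sampling is the expensive part)."""
    surf = surfaces.double_well_2d(barrier=2.0, ky=4.0)
    windows = umbrella.build_window_grid(
        (-1.5, 1.5), 0.25, (-0.75, 0.75), 0.25, force_constants=(20.0, 20.0)
    )
    synthetic.make_umbrella_dataset(
        surf, windows, n_per_window=2000, seed=42, step_size=0.12
    )
    return surf, windows


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
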