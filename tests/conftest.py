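import numpy as np
import pytest

from deltagamma import DeltaGammaParams, GammaParams, dg_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def synthetic_rainfall():
    """Synthetic stand-in for a two-month rainfall series: a seeded
    Δ(0.5, 2, 1) sample of size 58 (roughly half exact zeros)."""
    sample = dg_sample(DeltaGammaParams(0.5, GammaParams(2.0, 1.0)), 58, seed=7)
    assert sample.n1 >= 3
    return sample


@pytest.fixture(scope="session")
def synthetic_rainfall_file(tmp_path_factory, synthetic_rainfall):
    path = tmp_path_factory.mktemp("data") / "synthetic_rainfall.txt"
    path.write_text("\n".join(f"{v:.6f}" for v in synthetic_rainfall.values) + "\n")
    return path
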