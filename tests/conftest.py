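import numpy as np
import pytest

from dunet.config import generate_clear_image
from dunet.haze_synthesis import SynthesisParams, build_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clear_dir(tmp_path):
    """Ten small synthetic clear scenes on disk."""
    from dunet.haze_synthesis import save_image

    d = tmp_path / "clear"
    d.mkdir()
    for i in range(10):
        save_image(generate_clear_image(48, 48, seed=100 + i), d / f"img_{i:02d}.png")
    return d


@pytest.fixture
def tiny_dataset(tmp_path, clear_dir):
    """A built hazy/clear dataset with manifest (10 pairs, 48x48)."""
    params = SynthesisParams(beta=2.0, A=170 / 255, seed=7, smoothness=8.0)
    manifest = build_dataset(clear_dir, params, tmp_path / "data")
    return tmp_path / "data", manifest, params
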