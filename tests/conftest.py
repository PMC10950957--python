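import numpy as np
import pytest

from spikeloom import FrameStream, ModelConfig, StimulusSpec, make_stimulus


@pytest.fixture(scope="session")
def default_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def small_config():
    """A reduced geometry for fast pipeline tests (24x24 input)."""
    from spikeloom import build_layout

    side = 24
    dl = build_layout(side_length=side, max_rs=4).dl
    return ModelConfig(side_length=side, max_rs=4, dl=dl)


@pytest.fixture()
def constant_stream():
    frames = np.full((10, 100, 100), 128, dtype=np.uint8)
    return FrameStream(frames, fps=30.0)


@pytest.fixture()
def short_loom():
    spec = StimulusSpec(
        kind="looming", n_frames=20, start_size=10, end_size=60,
        object_intensity=40, background_intensity=220,
    )
    return make_stimulus(spec)
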