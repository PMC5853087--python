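import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cbppg.config import PipelineConfig
from cbppg.pipeline import train_default_skin_model
from cbppg import synthetic

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def skin_model(config):
    return train_default_skin_model(config)


@pytest.fixture(scope="session")
def short_scene():
    """One-second clean recording with a single skin ellipse."""
    script = synthetic.SceneScript(duration=1.0, fps=10.0, seed=3)
    video, truth = synthetic.render_video_pair(script)
    return script, video, truth
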