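import numpy as np
import pytest

import gaitkin as gk


@pytest.fixture(scope="session")
def small_cfg() -> gk.FishModelConfig:
    """Short noiseless clip: 0.3 s at 500 fps, 3 tail-beat cycles."""
    return gk.FishModelConfig(duration_s=0.3, fps=500)


@pytest.fixture(scope="session")
def small_video(small_cfg):
    frames, truth = gk.generate_video(small_cfg)
    return frames, truth


@pytest.fixture(scope="session")
def small_analysis(small_video, small_cfg):
    """Full pipeline run on the small noiseless clip, with debug artifacts."""
    frames, _ = small_video
    cfg = gk.PipelineConfig(fps=small_cfg.fps)
    trace, summary, reports, accepted, debug = gk.analyze_frames(
        frames, cfg, collect_debug=True)
    return dict(trace=trace, summary=summary, reports=reports,
                accepted=accepted, debug=debug, cfg=cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
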