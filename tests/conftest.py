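import numpy as np
import pytest

from kinetrack import imageproc, synthetic, tracker


@pytest.fixture(scope="session")
def default_scene():
    """The stock 64x64, 40-frame scene with one blob and one red marker."""
    cfg = synthetic.default_scene_config(seed=0)
    seq, gt = synthetic.make_scene(cfg)
    return cfg, seq, gt


@pytest.fixture(scope="session")
def default_track(default_scene):
    cfg, seq, gt = default_scene
    init = tracker.SearchWindow(tuple(gt.trajectories[0, 0]), cfg.blobs[0].axes)
    return tracker.track(seq, init), gt


@pytest.fixture(scope="session")
def warmed_gmm(default_scene):
    """GMM warmed on 30 blob-free background frames of the default scene."""
    from kinetrack import background

    cfg, _, _ = default_scene
    warm = synthetic.render_background(cfg, 30)
    model = background.init_gmm(imageproc.to_gray(warm[0]), K=3)
    for f in warm.frames[1:]:
        background.update_gmm(model, imageproc.to_gray(f))
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
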