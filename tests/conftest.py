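import numpy as np
import pytest

import endospec as es


@pytest.fixture(scope="session")
def camera():
    return es.default_camera()


@pytest.fixture(scope="session")
def checker30():
    """30-patch synthetic color checker on the default grid."""
    return es.make_color_checker(n_patches=30, seed=1)


@pytest.fixture(scope="session")
def rank3_model(camera):
    """Reconstructor fitted on an exactly 3-dimensional spectral family.

    Trained on quantization-free renders so the RGB-to-coefficient map
    lies exactly in the polynomial model class.
    """
    lib = es.make_color_checker(n_patches=60, seed=1, rank=3)
    rgbs = es.render_rgb(lib, camera, quantize=False)
    model = es.SpectralReconstructor(n_components=3).fit(lib, rgbs)
    return model


@pytest.fixture(scope="session")
def nbi_scene(camera):
    scene = es.make_endoscopic_scene("IPCL_V3_SCC", "nbi", size=(192, 192), seed=7)
    return scene, es.render_rgb(scene, camera)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
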