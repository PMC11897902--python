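import numpy as np
import pytest

from lemnaquant.config import PipelineConfig
from lemnaquant.synth import SceneManifest, TrialDesign, TubeScene


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def three_tube_manifest():
    return SceneManifest(
        tubes=[
            TubeScene(barcode="LG-0042", target_area_px=3000, depth_rows=35,
                      barcode_rotation_deg=7.0, barcode_contrast=(90, 160)),
            TubeScene(barcode="KA-100-3", target_area_px=0, depth_rows=0),
            TubeScene(barcode="FR-400-6", target_area_px=12000, depth_rows=60,
                      barcode_rotation_deg=-9.0),
        ]
    )


@pytest.fixture(scope="session")
def mini_design():
    """2 clones x 2 doses x 2 replicates over 5 imaging days."""
    return TrialDesign(
        clones=("France", "Kashmir"),
        doses_mM=(0.0, 100.0),
        replicates=2,
        schedule_days=(0, 1, 2, 3, 4),
        seed=11,
    )


@pytest.fixture(scope="session")
def mini_image_dir(tmp_path_factory, mini_design):
    """Rendered mini trial shared by the image-pipeline tests."""
    from lemnaquant.synth import simulate_trial_images

    out = tmp_path_factory.mktemp("mini_trial")
    truth = simulate_trial_images(mini_design, out)
    return out, truth
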