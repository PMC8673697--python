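import numpy as np
import pytest

import endobench as eb


@pytest.fixture(scope="session")
def sphere10():
    """The preset 10 cm bladder-like sphere phantom."""
    return eb.make_sphere_phantom(10.0, subdivisions=4)


@pytest.fixture(scope="session")
def sphere10_coarse():
    """Low-subdivision sphere for triangle-path rendering tests."""
    return eb.make_sphere_phantom(10.0, subdivisions=2)


@pytest.fixture(scope="session")
def tiny_config(tmp_path_factory):
    """A desk-scale synthesis config: short equatorial scan, small frames."""
    return eb.SynthesisConfig(
        output_dir=str(tmp_path_factory.mktemp("synth")),
        polar_range=(0.4 * np.pi, 0.6 * np.pi),
        velocity_cm_s=8.0,
        frame_rate_hz=5.0,
        width_px=64,
        height_px=64,
        texture_width=128,
        texture_height=128,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    """One complete synthesis run shared by evaluation tests."""
    return eb.synthesize(tiny_config)
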