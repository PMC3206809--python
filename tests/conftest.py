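import numpy as np
import pytest

import fibroscore as fs


@pytest.fixture(scope="session")
def invivo_index():
    """E_in_vivo index built from the packaged literature histology table."""
    return fs.build_invivo_index(fs.load_invivo_records())


@pytest.fixture(scope="session")
def published_epredict():
    return fs.load_published_epredict()


@pytest.fixture(scope="session")
def directions():
    return fs.load_marker_directions()


@pytest.fixture(scope="session")
def small_screen():
    """A 6-drug graded-efficacy screen, small enough for the whole suite."""
    design = fs.ScreenDesign(cells_per_condition=120, seed=3)
    drugs = fs.graded_panel(6, seed=3)
    table = fs.generate_screen(design, drugs)
    return design, drugs, table


@pytest.fixture(scope="session")
def small_profile(small_screen):
    _, _, table = small_screen
    return fs.compute_kr_profile(table)


@pytest.fixture(scope="session")
def small_sauc(small_profile, directions):
    return fs.compute_sauc(small_profile, directions)


@pytest.fixture(scope="session")
def small_invivo(small_screen):
    _, drugs, _ = small_screen
    return fs.build_invivo_index(fs.generate_invivo(drugs, noise_sd=0.0, seed=9))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
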