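import numpy as np
import pytest

from perfmoco.phantom import PhantomConfig, generate_series

# Desk-scale phantom: same physical anatomy as the default matrix, rendered
# at half resolution so pipeline tests stay within the suite's time budget.
TEST_MATRIX = (96, 128)
TEST_SPACING = 2.8
TEST_FRAMES = 40


def small_config(seed=0, **overrides):
    overrides.setdefault("matrix", TEST_MATRIX)
    overrides.setdefault("spacing", TEST_SPACING)
    overrides.setdefault("n_frames", TEST_FRAMES)
    return PhantomConfig(seed=seed, **overrides)


@pytest.fixture(scope="session")
def free_breathing_phantom():
    return generate_series(small_config(seed=1))


@pytest.fixture(scope="session")
def motion_free_phantom():
    return generate_series(small_config(seed=1, motion_mode="none"))


@pytest.fixture(scope="session")
def icasp_result(free_breathing_phantom):
    from perfmoco.moco_icasp import run_icasp

    return run_icasp(free_breathing_phantom.series)


@pytest.fixture(scope="session")
def quasip_result(free_breathing_phantom):
    from perfmoco.moco_quasip import run_quasip

    return run_quasip(free_breathing_phantom.series)


@pytest.fixture(scope="session")
def icasp_motion_free(motion_free_phantom):
    from perfmoco.moco_icasp import run_icasp

    return run_icasp(motion_free_phantom.series)


@pytest.fixture(scope="session")
def quasip_motion_free(motion_free_phantom):
    from perfmoco.moco_quasip import run_quasip

    return run_quasip(motion_free_phantom.series)


def mean_scores(table, measure, phase):
    sub = table[(table["measure"] == measure) & (table["phase"] == phase)]
    return float(sub["value"].mean())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140923)
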