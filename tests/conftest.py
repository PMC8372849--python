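import numpy as np
import pytest

from fetalpose import (PhantomSpec, PipelineConfig, detect_head_pose,
                       generate, load_biometry)


@pytest.fixture(scope="session")
def biometry_table():
    return load_biometry()


@pytest.fixture(scope="session")
def ga31(biometry_table):
    """(OFD, BPD, OD) at 31 weeks."""
    return biometry_table.lookup(31.0)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, identity-pose, decoy-free phantom at 31 weeks."""
    spec = PhantomSpec(ga=31.0, noise_sigma=0.0, odd_even_shift_mm=0.0,
                       decoys=0, seed=1)
    return generate(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom under the default study conditions (noise, motion, decoys)."""
    spec = PhantomSpec(ga=31.0, seed=7)
    return generate(spec)


@pytest.fixture(scope="session")
def clean_detection(clean_phantom):
    """Full-pipeline result on the clean phantom, shared across tests."""
    vol, truth = clean_phantom
    return detect_head_pose(vol, truth.ga), truth


@pytest.fixture()
def config():
    return PipelineConfig()


def truth_landmarks(truth):
    return {"b": truth.b, "left": truth.e_left, "right": truth.e_right}
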