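import numpy as np
import pytest

from tempcode import synthdata


@pytest.fixture(scope="session")
def program():
    return synthdata.TemporalProgram()


@pytest.fixture(scope="session")
def small_section(program):
    """A compact section at default SNR, shared across read-only tests."""
    spec = synthdata.SectionSpec(image_shape=(256, 256), n_nuclei=30)
    image, truth = synthdata.generate_section(spec, program, seed=11)
    return spec, image, truth


@pytest.fixture(scope="session")
def clean_section(program):
    """Noise-free, well-separated section for exact segmentation checks."""
    spec = synthdata.SectionSpec(image_shape=(256, 256), n_nuclei=12, snr=np.inf)
    image, truth = synthdata.generate_section(spec, program, seed=5)
    return spec, image, truth
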