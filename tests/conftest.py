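import numpy as np
import pytest

from cerephys import synth
from cerephys.core import StimulusProtocol


@pytest.fixture(scope="session")
def bimodal_sample():
    """650 soma sizes from the two-population GABAergic mixture."""
    spec = synth.MixtureSpec(((0.5, 11.9, 1.3), (0.5, 16.2, 2.0)))
    return synth.sample_soma_sizes(spec, 650, seed=42)


@pytest.fixture(scope="session")
def unimodal_sample():
    """118 soma sizes from a single glycinergic-like Gaussian."""
    return synth.sample_soma_sizes(synth.MixtureSpec(((1.0, 16.6, 2.0),)), 118, seed=43)


@pytest.fixture(scope="session")
def invivo_protocol():
    """400 light pulses of the 4-Hz / 3-s-bout / 7-s-recovery protocol."""
    proto = synth.make_stim_protocol(total_s=340.0)
    return StimulusProtocol(proto.onsets_s[:400], 25.0)


@pytest.fixture(scope="session")
def responsive_unit(invivo_protocol):
    """Inhomogeneous-Poisson unit with the responsive-Golgi rate profile."""
    profile = synth.RateProfile()
    duration = invivo_protocol.onsets_s[-1] + 1.0
    return synth.gen_poisson_train(profile, invivo_protocol, duration, seed=7)


@pytest.fixture(scope="session")
def intensity_table():
    return synth.gen_intensity_table(synth.IntensityPopSpec(), seed=11)
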