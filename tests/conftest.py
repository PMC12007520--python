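import numpy as np
import pytest
from dataclasses import replace

from aslquant.data import ASLTimingSpec, subtract_pairs
from aslquant.phantom import PhantomSpec, generate, noise_sd_for_snr


@pytest.fixture(scope="session")
def small_timing():
    """6-delay pCASL protocol used by most phantom tests."""
    return ASLTimingSpec(
        labelling="pcasl",
        label_duration=1.4,
        delays=(0.25, 0.5, 0.75, 1.0, 1.25, 1.5),
        repeats_per_delay=2,
    )


@pytest.fixture(scope="session")
def tiny_phantom(small_timing):
    """A small noiseless pure-GM phantom: (spec, raw series, m0, truth)."""
    spec = PhantomSpec(shape=(6, 6, 2), seed=0, timing=small_timing)
    series, m0, truth = generate(spec)
    return spec, series, m0, truth


@pytest.fixture(scope="session")
def tiny_noisy_diff(small_timing):
    """Differenced series from a small noisy phantom plus its truth."""
    spec = PhantomSpec(shape=(8, 8, 2), seed=42, timing=small_timing)
    spec = replace(spec, noise_sd=noise_sd_for_snr(spec, 10.0))
    series, m0, truth = generate(spec)
    return spec, subtract_pairs(series), truth
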