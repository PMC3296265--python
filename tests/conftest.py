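import numpy as np
import pytest

from decspec import preset, synthesize, add_noise


@pytest.fixture(scope="session")
def two_peak():
    return preset("two_peak")


@pytest.fixture(scope="session")
def five_peak():
    return preset("five_peak_31p")


@pytest.fixture(scope="session")
def eleven_peak():
    return preset("eleven_peak_31p")


@pytest.fixture(scope="session")
def clean_series():
    """Noise-free default-length series for each preset, by name."""
    return {
        name: synthesize(preset(name).model, preset(name).default_N)
        for name in ("two_peak", "five_peak_31p", "eleven_peak_31p")
    }


@pytest.fixture(scope="session")
def noisy_two_peak(two_peak):
    ts = synthesize(two_peak.model, two_peak.default_N)
    return add_noise(ts, 0.1, seed=1234)


def assert_params_close(result, model, rtol=1e-5, atol_scale=1e-6):
    """All (f, d, b, psi) within rtol relative of the model's table values.

    Zero-valued truths (e.g. zero phases) are compared absolutely, scaled by
    the largest magnitude of that parameter across peaks.
    """
    est = np.array([[pk.f, pk.d, pk.b, pk.psi] for pk in result.peaks])
    order = np.argsort(model.frequencies())
    truth = np.array(
        [[pk.f, pk.d, pk.b, pk.psi] for pk in model.peaks]
    )[order]
    for k in range(4):
        scale = np.abs(truth[:, k]).max()
        atol = atol_scale * (scale if scale > 0 else 1.0)
        np.testing.assert_allclose(est[:, k], truth[:, k], rtol=rtol, atol=atol)
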