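import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_edge():
    """Vertical free edge at x = 0, wound at x < 0."""
    from ccpol.polarity import EdgeReference
    return EdgeReference.vertical_line(0.0)


def von_mises_resultant_length(kappa: float) -> float:
    """Independent oracle for the von Mises mean resultant length.

    Direct numerical integration of E[cos theta] under the von Mises
    density (no Bessel-function shortcut), so it cross-checks both the
    sampler and the polarity index.
    """
    from scipy.integrate import quad
    num = quad(lambda t: np.cos(t) * np.exp(kappa * np.cos(t)), -np.pi, np.pi)[0]
    den = quad(lambda t: np.exp(kappa * np.cos(t)), -np.pi, np.pi)[0]
    return num / den
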