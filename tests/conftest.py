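import numpy as np
import pytest

from paleoproxy import radiocarbon_engine as rc
from paleoproxy import synthetic_population as sp


@pytest.fixture(scope="session")
def default_params():
    return sp.default_params()


@pytest.fixture(scope="session")
def default_run(default_params):
    """2000-year noiseless run at default productivity after 500-yr burn-in."""
    regime = sp.ProductivityRegime(1.0, 2_000, 0)
    return sp.simulate_forager_dynamics(default_params, regime, burn_in=500)


@pytest.fixture(scope="session")
def ladder_runs(default_params):
    """One 2000-year run per default productivity level."""
    runs = {}
    for prod in sp.DEFAULT_PRODUCTIVITY_LADDER:
        regime = sp.ProductivityRegime(prod, 2_000, 0)
        runs[prod] = sp.simulate_forager_dynamics(default_params, regime, burn_in=500)
    return runs


@pytest.fixture(scope="session")
def default_truth(default_params):
    """Concatenated four-regime trajectory over 10,000-5,881 cal BP."""
    segments = [(reg, default_params) for reg in sp.default_regime_ladder()]
    return sp.concatenate_regimes(segments, burn_in=500)


@pytest.fixture(scope="session")
def identity_curve():
    return rc.make_identity_curve(4_000, 12_000)


def dominant_period(values: np.ndarray) -> float:
    """Periodogram-based dominant period (1-year sampling)."""
    from scipy.signal import periodogram

    x = np.asarray(values, dtype=float)
    freq, power = periodogram(x - x.mean(), fs=1.0)
    return 1.0 / freq[1:][np.argmax(power[1:])]
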