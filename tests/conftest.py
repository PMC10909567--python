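import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from coralipm import synthetic, vital_rates
from coralipm.kernel import build_kernel


@pytest.fixture(scope="session")
def assemblage():
    """One synthetic tropical competitive assemblage: observations,
    recruit surveys, fecundity table and the generative parameters."""
    params = synthetic.preset_params("AT", "competitive", n_colonies=600,
                                     n_years=4, seed=11)
    obs, recruits = synthetic.simulate_survey(params)
    fec = synthetic.simulate_fecundity(params, 300, seed=12)
    return params, obs, recruits, fec


@pytest.fixture(scope="session")
def fitted_rates(assemblage):
    import warnings
    _, obs, recruits, fec = assemblage
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return vital_rates.fit_all(obs, recruits, fec)


@pytest.fixture(scope="session")
def fixture_kernel(fitted_rates):
    return build_kernel(fitted_rates, 200)


@pytest.fixture(scope="session")
def strategy_kernels():
    """True-rate kernels for one weedy and one stress-tolerant assemblage."""
    import warnings
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for strat in ("weedy", "stress_tolerant"):
            p = synthetic.preset_params("AS", strat, n_colonies=400,
                                        n_years=4, seed=21)
            obs, _ = synthetic.simulate_survey(p)
            sizes = np.array([o.size_t for o in obs])
            rates = vital_rates.rates_from_params(
                p, (float(sizes.min()), float(sizes.max())))
            out[strat] = build_kernel(rates, 200)
    return out
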