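import numpy as np
import pytest

from opiniondyn import (InterventionParams, EffectiveRates, effective_rates)


@pytest.fixture
def baseline() -> InterventionParams:
    """Baseline scenario parameters (all intervention offsets zero)."""
    return InterventionParams()


@pytest.fixture
def baseline_rates(baseline) -> EffectiveRates:
    return effective_rates(baseline)


def draw_valid_rates(rng: np.random.Generator) -> EffectiveRates:
    """One random effective-rate vector satisfying every model bound
    (alpha >= epsilon, beta > 0, xi + eta_bar > 0, rates within range)."""
    alpha = rng.uniform(0.01, 0.2)
    return EffectiveRates(
        alpha=alpha,
        beta=rng.uniform(0.02, 0.3),
        xi=rng.uniform(0.02, 0.3),
        gamma=rng.uniform(0.1, 0.9),
        eta_star=rng.uniform(0.01, 0.2),
        eta_bar=rng.uniform(0.0, 0.05),
        epsilon=rng.uniform(0.0, 0.8 * alpha),
        A=rng.uniform(0.005, 0.05),
    )


@pytest.fixture
def rates_sampler():
    return draw_valid_rates
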