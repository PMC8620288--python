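import numpy as np
import pytest

from sulforasim.cli_io import (
    DEFAULT_KINETICS,
    PRODUCT_CONVERSION_DEFAULTS,
    default_model_params,
)
from sulforasim.estimation import TimeSeriesDataset, default_fit_spec
from sulforasim.simulation import simulate

PRODUCTS = ["HighBP", "HighBF", "MedBF", "LowBF", "NoBF"]


@pytest.fixture(scope="session")
def product_params():
    """Default ModelParams per product, built once."""
    return {name: default_model_params(name) for name in PRODUCTS}


def true_values(product: str, names) -> dict[str, float]:
    """The generating values of fittable parameters under the defaults."""
    out = {}
    for k in names:
        out[k] = PRODUCT_CONVERSION_DEFAULTS[product].get(k, DEFAULT_KINETICS.get(k))
    return out


@pytest.fixture(scope="session")
def highbf_clean_series(product_params):
    """Noise-free HighBF excretion rates at 12 observation times."""
    times = np.linspace(40, 1400, 12)
    res = simulate(
        product_params["HighBF"],
        grid=np.concatenate([[0.0], times]),
        rtol=1e-8,
        atol=1e-10,
    )
    return times, res.excretion_rate[1:]


def make_dataset(product, times, rates, sd=None, participant="p00"):
    return TimeSeriesDataset(
        participant=participant, product=product, times=times, rates=rates, sd=sd
    )


@pytest.fixture(scope="session")
def informative_times():
    """Sampling grid covering both absorption phases and the tail."""
    return np.concatenate(
        [np.linspace(40, 280, 5), np.linspace(330, 700, 6), np.linspace(800, 1500, 4)]
    )


__all__ = ["PRODUCTS", "true_values", "make_dataset", "default_fit_spec"]
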