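import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")

from dielkin.permittivity_models import HNComponent, eval_component
from dielkin.synthetic_data import preset_card


@pytest.fixture(scope="session")
def dia_card():
    return preset_card("dia_like")


@pytest.fixture(scope="session")
def nor_card():
    return preset_card("nor_like")


@pytest.fixture(scope="session")
def tetra_card():
    return preset_card("tetra_like")


def brute_force_tau_max(a: float, b: float, tau_hn: float = 1.0) -> float:
    """Independent oracle: dense two-stage grid argmax of the HN loss."""
    comp = HNComponent("alpha", 1.0, tau_hn, a, b)
    centre = -np.log10(2 * np.pi * tau_hn)
    lg = np.linspace(centre - 6, centre + 6, 4001)
    loss = eval_component(comp, 10.0 ** lg).imag
    i = int(np.argmax(loss))
    lg2 = np.linspace(lg[max(i - 2, 0)], lg[min(i + 2, lg.size - 1)], 4001)
    loss2 = eval_component(comp, 10.0 ** lg2).imag
    nu_pk = 10.0 ** lg2[int(np.argmax(loss2))]
    return 1.0 / (2 * np.pi * nu_pk)
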