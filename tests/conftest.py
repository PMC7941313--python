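import numpy as np
import pytest

from vesifit.models import (
    BilayerParams,
    LamellarOrganization,
    MixtureComponent,
    MixtureModel,
    SchulzSizeDistribution,
)
from vesifit import simulate


@pytest.fixture(scope="session")
def dmpc30_bilayer() -> BilayerParams:
    """An asymmetric-headgroup parameter set typical for extruded DMPC."""
    return BilayerParams(
        z_H1=1.86, sigma_H1=0.27, A2_over_A1=1.78,
        z_H2=1.71, sigma_H2=0.13, rho_r=1.53, sigma_C=0.42,
    )


@pytest.fixture(scope="session")
def symmetric_bilayer() -> BilayerParams:
    return BilayerParams(
        z_H1=2.0, sigma_H1=0.2, A2_over_A1=1.0,
        z_H2=2.0, sigma_H2=0.2, rho_r=1.5, sigma_C=0.4,
    )


@pytest.fixture(scope="session")
def schulz_50_5() -> SchulzSizeDistribution:
    return SchulzSizeDistribution(R=50.0, sigma=5.0)


@pytest.fixture(scope="session")
def mlv7_organization() -> LamellarOrganization:
    return LamellarOrganization(
        states=((0.35, 1), (0.05, 2), (0.05, 3), (0.05, 4), (0.05, 5), (0.1, 6), (0.35, 7)),
        d=6.5,
        eta=0.10,
    )


@pytest.fixture(scope="session")
def suv_component(schulz_50_5, symmetric_bilayer) -> MixtureComponent:
    return MixtureComponent(
        nu=1.0, size=schulz_50_5, bilayer=symmetric_bilayer,
        lamellar=LamellarOrganization.suv(),
    )


@pytest.fixture(scope="session")
def mlv_component(schulz_50_5, symmetric_bilayer, mlv7_organization) -> MixtureComponent:
    return MixtureComponent(
        nu=1.0, size=schulz_50_5, bilayer=symmetric_bilayer,
        lamellar=mlv7_organization,
    )


@pytest.fixture(scope="session")
def suv_model(suv_component) -> MixtureModel:
    return MixtureModel(components=(suv_component,))


@pytest.fixture(scope="session")
def mlv_model(mlv_component) -> MixtureModel:
    return MixtureModel(components=(mlv_component,))


@pytest.fixture(scope="session")
def s_grid() -> np.ndarray:
    return np.geomspace(0.01, 7.0, 300)


@pytest.fixture(scope="session")
def benchmark_suv():
    """(noisy curve, truth model) for the SUV-only validation case."""
    return simulate.benchmark_cases(seed=1)["suv"]


@pytest.fixture(scope="session")
def benchmark_mlv7():
    """(noisy curve, truth model) for the SUV+MLV(<=7) validation case."""
    return simulate.benchmark_cases(seed=1)["mlv7"]


def random_bilayers(n: int, seed: int = 0):
    """n random valid bilayer parameter sets (for oracle sweeps)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            BilayerParams(
                z_H1=rng.uniform(1.5, 2.5),
                sigma_H1=rng.uniform(0.1, 0.3),
                A2_over_A1=rng.uniform(0.5, 2.5),
                z_H2=rng.uniform(1.5, 2.5),
                sigma_H2=rng.uniform(0.1, 0.3),
                rho_r=rng.uniform(0.8, 2.5),
                sigma_C=rng.uniform(0.25, 0.8),
            )
        )
    return out
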