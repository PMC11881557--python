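import numpy as np
import pytest

import pippk as pk

TABLE2_THETA = dict(cl=7.1, v1=17.2, q=3.25, v2=4.79)
TABLE2_OMEGA2 = {"cl": 0.287**2, "v1": 0.41**2}
TABLE2_SIGMA2 = 0.371**2


@pytest.fixture(scope="session")
def final_model() -> pk.ModelSpec:
    """Packaged final model: allometry + CrCL power on CL + IIV/IOV + prop error."""
    return pk.load_final_model()


@pytest.fixture(scope="session")
def no_iov_model(final_model) -> pk.ModelSpec:
    """Final model without inter-occasion variability (intra-operative conditions)."""
    return pk.ModelSpec(
        theta=final_model.theta,
        covariate_effects=final_model.covariate_effects,
        random=pk.RandomEffectSpec(omega2=dict(final_model.random.omega2),
                                   sigma2_prop=final_model.random.sigma2_prop))


@pytest.fixture(scope="session")
def study_dataset(final_model) -> pk.PKDataset:
    """One study-like opportunistic dataset (34 subjects) under the final model."""
    return pk.make_study(final_model, seed=0)


@pytest.fixture(scope="session")
def table2_params() -> pk.StructuralParams:
    return pk.StructuralParams(**TABLE2_THETA)


def random_params(rng: np.random.Generator) -> pk.StructuralParams:
    """Parameters log-uniform within 10x of the published typical values."""
    vals = {k: v * np.exp(rng.uniform(-np.log(10), np.log(10)))
            for k, v in TABLE2_THETA.items()}
    return pk.StructuralParams(**vals)


def random_regimen(rng: np.random.Generator) -> list[pk.DoseEvent]:
    n = int(rng.integers(1, 6))
    t = 0.0
    doses = []
    for _ in range(n):
        doses.append(pk.DoseEvent(start_time=t,
                                  amount=float(rng.uniform(100, 4000)),
                                  duration=float(rng.uniform(0.2, 2.0))))
        t += float(rng.uniform(1.0, 4.0))
    return doses
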