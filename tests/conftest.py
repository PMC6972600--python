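import numpy as np
import pytest

from bmdrisk.models import (
    CriticalEffectSize,
    DoseGroup,
    DoseResponseDataset,
    ModelParams,
    predict,
)

CES = CriticalEffectSize(0.5)


@pytest.fixture
def ces():
    return CES


@pytest.fixture
def exp_params():
    return ModelParams("exponential", a=2.0, ced=10.0, c=5.0, d=1.0, log_sd=0.3)


@pytest.fixture
def hill_params():
    return ModelParams("hill", a=2.0, ced=10.0, c=5.0, d=1.5, log_sd=0.3)


def random_valid_params(rng, family=None):
    """One random parameter draw with the CED defined at CES=0.5."""
    fam = family or rng.choice(["exponential", "hill"])
    return ModelParams(
        family=fam,
        a=float(rng.uniform(0.05, 5.0)),
        ced=float(rng.uniform(0.5, 200.0)),
        c=float(rng.uniform(1.6, 20.0)),  # keeps CES=0.5 < c-1
        d=float(rng.uniform(0.25, 4.0)),
        log_sd=float(rng.uniform(0.05, 1.0)),
    )


def noise_free_dataset(truth, ces, doses, n_per_group=5, covariate=None):
    groups = tuple(
        DoseGroup(
            dose=d,
            covariate=covariate,
            responses=tuple([predict(truth, ces, d)] * n_per_group),
        )
        for d in doses
    )
    return DoseResponseDataset(groups)


@pytest.fixture
def six_group_dataset():
    """Small noisy single-level fixture used by the grid-search oracle."""
    rng = np.random.default_rng(42)
    truth = ModelParams("exponential", a=0.3, ced=12.0, c=4.0, d=1.0, log_sd=0.3)
    groups = []
    for d in (0.0, 1.0, 3.0, 10.0, 30.0, 100.0):
        med = predict(truth, CES, d)
        groups.append(
            DoseGroup(dose=d, responses=tuple(med * np.exp(rng.normal(0, 0.3, 8))))
        )
    return DoseResponseDataset(tuple(groups))
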