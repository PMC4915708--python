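import numpy as np
import pytest

from copdcea.parameters import (
    LIVING_STAGES,
    CohortSpec,
    DiscountSpec,
    ModelParameters,
    MortalityModel,
    PRPolicy,
    SmokingDynamics,
    StageParameters,
    TransitionModel,
)
from copdcea.synthetic_data import make_baseline_fixture


@pytest.fixture(scope="session")
def baseline():
    """The packaged baseline parameter set (loaded once per session)."""
    return make_baseline_fixture()


def make_toy_params(
    *,
    q: float = 0.0,
    trans_g2: float = 0.0,
    trans_g3: float = 0.0,
    utility: tuple[float, float] = (1.0, 1.0),
    exac_prob: float = 0.0,
    cost: float = 0.0,
    rate: float = 0.0,
    start_age: int = 60,
    max_age: int = 110,
    cessation: float = 0.0,
    relapse: float = 0.0,
    pr_policy: PRPolicy | None = None,
) -> ModelParameters:
    """Minimal hand-built parameter set: everyone enters GOLD2 at one age,
    with constant mortality and progression probabilities everywhere."""
    stage_params = {
        stage: StageParameters(exac_prob, utility[0], utility[1], cost)
        for stage in LIVING_STAGES
    }
    probs = np.zeros((1, 3, 3, 2))
    probs[:, 0] = trans_g2
    probs[:, 1] = trans_g3
    transitions = TransitionModel([30], probs)
    n_ages = max_age - 30 + 1
    mortality = MortalityModel(30, np.full((n_ages, 3, 3), q))
    band = f"{start_age}-{start_age}"
    cohort = CohortSpec(
        stage_prevalence=np.array([1.0, 0.0, 0.0]),
        smoking_distribution=np.array([[1.0, 0, 0], [1.0, 0, 0], [1.0, 0, 0]]),
        age_distribution={stage: {band: 1.0} for stage in LIVING_STAGES},
        max_age=max_age,
    )
    return ModelParameters(
        stage_params=stage_params,
        transitions=transitions,
        mortality=mortality,
        smoking=SmokingDynamics(cessation, relapse),
        cohort=cohort,
        discount=DiscountSpec(annual_rate=rate),
        pr_policy=pr_policy if pr_policy is not None else PRPolicy(),
    ).validate()
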