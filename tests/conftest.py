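import numpy as np
import pytest

from netbridge.behaviour import BehaviourTable
from netbridge.synthetic_data import SyntheticSpec, make_behaviour

# reference ADI-R domain-score correlations (Social, Communication, RRBI)
DOMAIN_CORR = np.array([
    [1.00, 0.66, 0.38],
    [0.66, 1.00, 0.36],
    [0.38, 0.36, 1.00],
])
DOMAIN_TRAITS = ["Social", "Communication", "RRBI"]


@pytest.fixture(scope="session")
def domain_corr() -> np.ndarray:
    return DOMAIN_CORR.copy()


@pytest.fixture(scope="session")
def domain_behaviour() -> BehaviourTable:
    """n=172 behaviour table whose sample correlation equals DOMAIN_CORR exactly."""
    spec = SyntheticSpec(n_subjects=172, trait_names=DOMAIN_TRAITS,
                         target_corr=DOMAIN_CORR, exact_corr=True, seed=20)
    return make_behaviour(spec)


def exact_behaviour(corr, traits, n=200, seed=0) -> BehaviourTable:
    spec = SyntheticSpec(n_subjects=n, trait_names=list(traits),
                         target_corr=np.asarray(corr, float),
                         exact_corr=True, seed=seed)
    return make_behaviour(spec)
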