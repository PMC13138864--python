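import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crtlm import ClusterSizeModel, CorrelationSpec, DesignSpec, MissingnessSpec

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: marginal observational probabilities with 40% dropout by the last visit
DELTA4 = (1.00, 0.85, 0.70, 0.66, 0.63, 0.60)


@pytest.fixture
def design_t3() -> DesignSpec:
    """Reference design: 3 visits at t = 0, 1, 2, slope difference 0.1."""
    return DesignSpec(p=0.5, sigma2=1.0, beta4=0.1, alpha=0.05,
                      power_target=0.8, times=(0, 1, 2))


@pytest.fixture
def corr_r1_cs() -> CorrelationSpec:
    """CS within-subject 0.30, ICC 0.05, between-period 0.025."""
    return CorrelationSpec(structure="CS", rho1=0.30, rho2=0.05, rho3=0.025)


@pytest.fixture
def cluster_j5() -> ClusterSizeModel:
    return ClusterSizeModel.fixed(5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def random_trial(rng, n_clusters=2, subjects=2, T=3, p=0.5, miss_prob=0.0):
    """Small random trial for oracle comparisons."""
    from crtlm import TrialData

    times = np.sort(rng.uniform(0, 3, T))
    arm = (rng.random(n_clusters) < p).astype(int)
    if arm.sum() == 0:
        arm[0] = 1
    if arm.sum() == n_clusters:
        arm[0] = 0
    S = n_clusters * subjects
    cluster_of = np.repeat(np.arange(n_clusters), subjects)
    y = rng.normal(size=(S, T))
    m = rng.random((S, T)) >= miss_prob
    # keep the design full rank: one fully observed subject in each arm
    for a in (0, 1):
        subj = np.flatnonzero(arm[cluster_of] == a)[0]
        m[subj, :] = True
    return TrialData(times=times, arm=arm, cluster_of=cluster_of,
                     y=np.where(m, y, np.nan), observed=m)
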