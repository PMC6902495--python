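import numpy as np
import pytest

from augseq import EndpointModel, LookCounts, SpendingPlan, TrialDataset


@pytest.fixture
def demo_model() -> EndpointModel:
    """Small-trial assumed model: sigma 18, rho13 = rho23 = 0.5, rho12 = 0."""
    return EndpointModel(
        sigmas=[18.0, 18.0, 18.0],
        corr=[[1.0, 0.0, 0.5], [0.0, 1.0, 0.5], [0.5, 0.5, 1.0]],
        means_control=[0.0, 0.0, 0.0],
        means_active=[0.0, 0.0, 0.0],
    )


@pytest.fixture
def demo_plan() -> SpendingPlan:
    return SpendingPlan(alphaL_cum=[0.200, 0.600, 0.975], alphaU_cum=[0.000, 0.001, 0.025])


@pytest.fixture
def uniform_model() -> EndpointModel:
    """START-style model: sigma 20, exchangeable correlation 0.5."""
    return EndpointModel.uniform(K=3, sigma=20.0, rho=0.5)


def make_monotone_dataset(
    model: EndpointModel,
    counts_per_arm,
    rng: np.random.Generator,
    delta: float = 0.0,
) -> TrialDataset:
    """Dataset with an exact monotone missingness pattern: per arm, the first
    N_K rows have all endpoints, the next N_{K-1} - N_K lack the final one,
    and so on.  Entry times are zero; restriction by time is not used."""
    counts = np.atleast_2d(np.asarray(counts_per_arm, dtype=int))
    if counts.shape[0] == 1:
        counts = np.vstack([counts, counts])
    K = model.K
    chol = np.linalg.cholesky(model.covariance())
    blocks = []
    arms = []
    for arm in (0, 1):
        n_arm = int(counts[arm, 0])
        vals = rng.standard_normal((n_arm, K)) @ chol.T + model.means(arm)
        if arm == 1:
            vals[:, K - 1] += delta
        for k in range(1, K):
            vals[int(counts[arm, k]):, k] = np.nan
        blocks.append(vals)
        arms.append(np.full(n_arm, arm))
    values = np.vstack(blocks)
    return TrialDataset(
        values=values,
        arms=np.concatenate(arms),
        entries=np.zeros(values.shape[0]),
        lags=tuple(0.0 for _ in range(K)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
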