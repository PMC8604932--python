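import numpy as np
import pandas as pd
import pytest

from compnoise.io import CountMatrix
from compnoise.model import ModelSpec, SizeFactors, fit_noise_model
from compnoise.simulate import preset_scenarios, simulate_dataset


def model_counts(
    seed,
    G=80,
    N=240,
    n_batches=4,
    logmu_mean=1.0,
    logmu_sd=1.0,
    trend=(-0.8, -0.5),
    sigma_eps=0.5,
    theta=0.0,
    s_logsd=0.2,
):
    """Draw counts straight from the model hierarchy; returns truth too."""
    rng = np.random.default_rng(seed)
    logmu = rng.normal(logmu_mean, logmu_sd, G)
    eps = rng.normal(0, sigma_eps, G) if sigma_eps > 0 else np.zeros(G)
    logdelta = trend[0] + trend[1] * logmu + eps
    mu, delta = np.exp(logmu), np.exp(logdelta)
    s = np.exp(rng.normal(0, s_logsd, N)) if s_logsd > 0 else np.ones(N)
    s /= s.mean()
    batch = np.repeat(np.arange(n_batches), N // n_batches)
    if theta > 0:
        nu = rng.gamma(1 / theta, s * theta)
    else:
        nu = s.copy()
    rho = rng.gamma(1 / delta[:, None], delta[:, None], (G, N))
    x = rng.poisson(nu[None, :] * mu[:, None] * rho)
    genes = [f"g{i:03d}" for i in range(G)]
    cells = [f"c{j:04d}" for j in range(N)]
    cm = CountMatrix(x, genes, cells)
    meta = pd.DataFrame(
        {"cell_id": cells, "strain": "WT", "replicate": [f"r{b}" for b in batch]}
    )
    truth = {"mu": mu, "delta": delta, "eps": eps, "s": s, "nu": nu, "theta": theta}
    return cm, meta, truth


SHORT_SPEC = ModelSpec(n_iter=600, burn_in=300, thin=3, seed=42)


@pytest.fixture(scope="session")
def model_fit():
    """One short fit on model-simulated data, shared across tests."""
    cm, meta, truth = model_counts(seed=1)
    sf = SizeFactors(truth["s"], cm.cell_ids)
    ps = fit_noise_model(cm, meta, sf, SHORT_SPEC)
    return cm, meta, truth, ps


@pytest.fixture(scope="session")
def redundant_dataset():
    """Small redundant-pair dataset shared by pipeline-level tests."""
    design = preset_scenarios(
        "redundant_pair", seed=5, n_genes=150, cells_per_replicate=40,
        n_shared=20, n_private=10,
    )
    return simulate_dataset(design)
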