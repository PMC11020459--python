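import numpy as np
import pytest

import fhsae


@pytest.fixture(scope="session")
def emdhs_table():
    """One study-scale synthetic dataset: 83 areas, 6 non-sampled."""
    return fhsae.simulate_areas(fhsae.emdhs_like_config(seed=11))


@pytest.fixture(scope="session")
def fast_mcmc():
    """Small MCMC budget for unit tests (convergence-checked elsewhere)."""
    return fhsae.MCMCConfig(n_iter=3000, burn_in=600, n_chains=1, seed=5)


@pytest.fixture(scope="session")
def emdhs_fit(emdhs_table, fast_mcmc):
    """A logit-link fit of the session fixture, GVF-smoothed variances."""
    table, truth = emdhs_table
    direct = fhsae.compute_direct(table)
    gvf = fhsae.fit_gvf(direct)
    psi = fhsae.select_variance(direct, gvf, "gvf")
    data = fhsae.make_fh_data(table, direct, psi)
    samples = fhsae.run_mcmc(data, "logit", config=fast_mcmc)
    return {
        "table": table, "truth": truth, "direct": direct, "gvf": gvf,
        "data": data, "samples": samples,
    }


@pytest.fixture
def identity_fixture():
    """Matched-model data generated directly from the identity-link FH model."""
    rng = np.random.default_rng(42)
    m = 40
    X = np.column_stack([np.ones(m), rng.uniform(-1, 1, (m, 2))])
    beta = np.array([0.35, 0.08, -0.12])
    sigma2 = 0.01
    theta = X @ beta + rng.normal(0, np.sqrt(sigma2), m)
    psi = rng.uniform(0.002, 0.01, m)
    p = theta + rng.normal(0, np.sqrt(psi))
    return fhsae.FHData(p_direct=p, psi=psi, X=X), beta, sigma2
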