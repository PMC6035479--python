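import numpy as np
import pytest

from remvar import (
    CovariateSpec,
    NormalRandomEffect,
    SimulationDesign,
    fit_random_intercept,
    make_af_like_fixture,
    make_dataset,
)


@pytest.fixture(scope="session")
def small_design():
    """20 clusters x 25 subjects, one subject and one cluster covariate."""
    return SimulationDesign(
        n_clusters=20,
        cluster_size=25,
        beta={"(Intercept)": -1.0, "x": 0.5, "z": 0.3},
        covariates={
            "x": CovariateSpec("normal", "subject"),
            "z": CovariateSpec("bernoulli", "cluster", p=0.5),
        },
        random_effect=NormalRandomEffect(0.6),
        family="binomial",
        seed=20240101,
    )


@pytest.fixture(scope="session")
def small_ds(small_design):
    ds, _ = make_dataset(small_design)
    return ds


@pytest.fixture(scope="session")
def small_fit(small_ds):
    return fit_random_intercept(small_ds, family="binomial", n_quad=15)


@pytest.fixture(scope="session")
def af_ds():
    return make_af_like_fixture(seed=7)


@pytest.fixture(scope="session")
def af_fit(af_ds):
    return fit_random_intercept(af_ds, family="binomial", n_quad=15)


@pytest.fixture(scope="session")
def boot_ds():
    """Tiny dataset sized for repeated bootstrap refits."""
    design = SimulationDesign(
        n_clusters=25,
        cluster_size=20,
        beta={"(Intercept)": -0.4},
        covariates={},
        random_effect=NormalRandomEffect(0.5),
        family="binomial",
        seed=99,
    )
    ds, _ = make_dataset(design)
    return ds


def bruteforce_marginal_loglik(ds, beta_by_col, sigma_u, n_grid=10001, width=8.0):
    """Independent dense-grid (trapezoid) marginal log-likelihood oracle.

    Integrates each cluster's conditional likelihood times the normal
    random-intercept density over u in +/- width*sigma_u, entirely apart
    from the package's quadrature code path.
    """
    from scipy.special import logsumexp
    from scipy.stats import norm

    frame = ds.frame
    eta0 = np.full(len(frame), beta_by_col["(Intercept)"], dtype=float)
    for col, b in beta_by_col.items():
        if col != "(Intercept)":
            eta0 += b * frame[col].to_numpy(dtype=float)
    y = frame[ds.outcome].to_numpy(dtype=float)

    u = np.linspace(-width * sigma_u, width * sigma_u, n_grid)
    du = u[1] - u[0]
    # trapezoid weights in log space
    logw = np.full(n_grid, np.log(du))
    logw[0] = logw[-1] = np.log(du / 2.0)

    total = 0.0
    for _, idx in frame.groupby(ds.cluster, observed=True).indices.items():
        eta = eta0[idx][:, None] + u[None, :]
        ll_cond = (y[idx][:, None] * eta - np.logaddexp(0.0, eta)).sum(axis=0)
        total += logsumexp(ll_cond + norm.logpdf(u, scale=sigma_u) + logw)
    return total
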