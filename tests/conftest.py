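"""Shared fixtures: attribute scheme, tiny bundled dataset, quadrature oracle."""

import numpy as np
import pytest

from dcewtp import build_attribute_scheme, read_choice_data
from dcewtp.pipeline import make_fixtures


@pytest.fixture(scope="session")
def scheme():
    return build_attribute_scheme()


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The bundled 5-respondent, 4-task fixture, generated once per session."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return make_fixtures(seed=1, outdir=outdir)


@pytest.fixture(scope="session")
def tiny_dataset(fixture_paths):
    return read_choice_data(fixture_paths["data"])


def gauss_hermite_loglik(dataset, params, random_contrast, n_nodes=64, scenario=None):
    """Independent oracle: exact 1-D mixing integral by Gauss-Hermite quadrature.

    Valid when exactly one WTP contrast is random (``random_contrast``) and
    the scale is degenerate (``scale_sigma == 0``).  Evaluates, respondent by
    respondent and node by node, the product over tasks of the chosen
    alternative's logit probability — a plain-loop implementation sharing no
    code with the simulated likelihood.
    """
    scheme = dataset.scheme
    assert params.scale_sigma == 0
    r = scheme.contrast_names.index(random_contrast)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    z = np.sqrt(2.0) * nodes
    w = weights / np.sqrt(np.pi)
    alpha = np.exp(params.scale_mu)

    total = 0.0
    for g in dataset.to_panel(scenario):
        n, T, A, K = g.X.shape
        for i in range(n):
            L_i = 0.0
            for j in range(n_nodes):
                beta = params.wtp_mean.copy()
                beta[r] += params.wtp_sd[r] * z[j]
                prod = 1.0
                for t in range(T):
                    v = np.array([
                        alpha * (g.X[i, t, a] @ beta - g.cost_eur[i, t, a])
                        for a in range(A)
                    ])
                    e = np.exp(v - v.max())
                    prod *= e[g.chosen[i, t]] / e.sum()
                L_i += w[j] * prod
            total += np.log(L_i)
    return total


@pytest.fixture(scope="session")
def gh_oracle():
    return gauss_hermite_loglik
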