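import numpy as np
import pytest

from selexrbm import rbm, seqdata
from selexrbm.drelu import DReLUParams


def random_params(L, M, seed, field_scale=0.5, weight_scale=0.5):
    """A random but well-conditioned RBM for oracle tests."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, field_scale, (L, 4))
    w = rng.normal(0, weight_scale, (M, L, 4))
    drelu = DReLUParams(
        rng.uniform(0.5, 2.0, M), rng.uniform(0.5, 2.0, M),
        rng.normal(0, 0.5, M), rng.normal(0, 0.5, M))
    return rbm.RBMParams(g, w, drelu)


def fields_only_params(g):
    g = np.asarray(g, dtype=float)
    M = 0
    return rbm.RBMParams(
        g, np.zeros((M, g.shape[0], 4)),
        DReLUParams(np.ones(M), np.ones(M), np.zeros(M), np.zeros(M)))


@pytest.fixture
def tiny_params():
    """L=3, M=2 model, enumerable exactly."""
    return random_params(3, 2, seed=1)


@pytest.fixture
def small_table():
    return seqdata.RoundTable(
        ["AAAA", "CCCC", "GGGG", "AAAT"], np.array([5, 2, 1, 1]))


def enumerate_probs(params):
    """Exact normalized p(s) over all sequences (analytic marginals)."""
    from scipy.special import logsumexp
    codes = rbm.enumerate_codes(params.L)
    ull = rbm.unnormalized_log_likelihood(params, codes)
    return codes, np.exp(ull - logsumexp(ull))


def quadrature_ull(params, codes):
    """Independent brute-force score: numerical quadrature over each
    hidden unit instead of the closed-form marginal."""
    from scipy.integrate import quad
    d = params.drelu
    out = []
    for c in np.atleast_2d(codes):
        val = params.g[np.arange(params.L), c].sum()
        I = params.w[:, np.arange(params.L), c].sum(axis=1) if params.M else []
        for mu in range(params.M):
            def f(h, mu=mu):
                hp, hm = max(h, 0.0), min(h, 0.0)
                U = (0.5 * d.gamma_plus[mu] * hp**2
                     + 0.5 * d.gamma_minus[mu] * hm**2
                     + d.theta_plus[mu] * hp + d.theta_minus[mu] * hm)
                return np.exp(-U + h * I[mu])
            a, _ = quad(f, 0, np.inf, epsabs=1e-13, epsrel=1e-13)
            b, _ = quad(f, -np.inf, 0, epsabs=1e-13, epsrel=1e-13)
            val += np.log(a + b)
        out.append(val)
    return np.array(out)
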