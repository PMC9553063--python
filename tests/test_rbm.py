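"""RBM energies, marginals, sampling and partition-function estimation,
checked against enumeration and quadrature oracles on tiny models."""

import numpy as np
import pytest
from scipy.special import logsumexp

from selexrbm import rbm, seqdata
from selexrbm.drelu import DReLUParams

from conftest import (enumerate_probs, fields_only_params, quadrature_ull,
                      random_params)


class TestHiddenInput:
    def test_zero_weights_give_zero_input(self, tiny_params):
        p = tiny_params.copy()
        p.w[:] = 0.0
        I = rbm.hidden_input(p, np.array([[0, 1, 2]], dtype=np.int8))
        assert np.all(I == 0)

    def test_single_weight_entry(self):
        p = random_params(4, 1, seed=0)
        p.w[:] = 0.0
        p.w[0, 2, 2] = 2.5  # unit 1, site 3, nucleotide G
        I = rbm.hidden_input(p, seqdata.encode("AAGA"))
        assert I[0, 0] == pytest.approx(2.5)
        I0 = rbm.hidden_input(p, seqdata.encode("AATA"))
        assert I0[0, 0] == 0.0

    def test_matches_loop_free_oracle(self, tiny_params):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 4, size=(10, 3)).astype(np.int8)
        I = rbm.hidden_input(tiny_params, codes)
        for n, c in enumerate(codes):
            for mu in range(tiny_params.M):
                expected = sum(tiny_params.w[mu, i, c[i]] for i in range(3))
                assert I[n, mu] == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self, tiny_params):
        with pytest.raises(ValueError):
            rbm.hidden_input(tiny_params, seqdata.encode("ACGT"))


class TestMarginalLikelihood:
    def test_fields_only_model(self):
        g = np.random.default_rng(0).normal(0, 1, (5, 4))
        p = fields_only_params(g)
        codes = seqdata.encode(["ACGTA", "TTTTT"])
        ull = rbm.unnormalized_log_likelihood(p, codes)
        for n, c in enumerate(codes):
            assert ull[n] == pytest.approx(
                g[np.arange(5), c].sum(), rel=1e-12)

    def test_matches_quadrature_and_normalizes(self, tiny_params):
        codes, probs = enumerate_probs(tiny_params)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)
        some = codes[::7]
        assert rbm.unnormalized_log_likelihood(tiny_params, some) == \
            pytest.approx(quadrature_ull(tiny_params, some), abs=1e-8)

    def test_gauge_shift_preserves_ranking(self, tiny_params):
        p = tiny_params.copy()
        codes = rbm.enumerate_codes(3)
        before = rbm.unnormalized_log_likelihood(p, codes)
        p.g[1, :] += 3.7  # constant shift of one site's fields
        after = rbm.unnormalized_log_likelihood(p, codes)
        assert after == pytest.approx(before + 3.7, rel=1e-12)

    def test_differences_independent_of_log_Z(self, tiny_params):
        codes = rbm.enumerate_codes(3)[:5]
        p = tiny_params.copy()
        p.log_Z = 0.0
        diffs0 = np.diff(rbm.log_likelihood(p, codes))
        p.log_Z = 123.4
        assert np.diff(rbm.log_likelihood(p, codes)) == pytest.approx(
            diffs0, rel=1e-12)


class TestLogZ:
    def test_fields_only_exact_with_zero_se(self):
        g = np.random.default_rng(1).normal(0, 1, (4, 4))
        p = fields_only_params(g)
        lz, se = rbm.estimate_log_Z(p, seed=0)
        assert se == 0.0
        assert lz == pytest.approx(logsumexp(g, axis=1).sum(), rel=1e-12)

    def test_ais_within_three_se_of_enumeration(self, tiny_params):
        exact = rbm.exact_log_Z(tiny_params)
        est, se = rbm.estimate_log_Z(tiny_params, n_steps=500, n_chains=200,
                                     seed=3)
        assert abs(est - exact) < 3 * max(se, 1e-3)

    def test_chain_count_consistency(self, tiny_params):
        e1, s1 = rbm.estimate_log_Z(tiny_params, n_steps=300, n_chains=100,
                                    seed=5)
        e2, s2 = rbm.estimate_log_Z(tiny_params, n_steps=300, n_chains=200,
                                    seed=6)
        assert abs(e1 - e2) < 3 * np.hypot(s1, s2) + 1e-3

    def test_invalid_counts_rejected(self, tiny_params):
        with pytest.raises(ValueError):
            rbm.estimate_log_Z(tiny_params, n_steps=0)


class TestConditionals:
    def test_fields_only_site_frequencies(self):
        rng = np.random.default_rng(2)
        g = rng.normal(0, 1, (3, 4))
        p = random_params(3, 1, seed=2)
        p.g = g
        p.w[:] = 0.0
        h = np.zeros((100_000, 1))
        s = rbm.sample_s_given_h(p, h, rng)
        soft = np.exp(g) / np.exp(g).sum(axis=1, keepdims=True)
        for i in range(3):
            emp = np.bincount(s[:, i], minlength=4) / len(s)
            sigma = np.sqrt(soft[i] * (1 - soft[i]) / len(s))
            assert np.all(np.abs(emp - soft[i]) < 4 * sigma + 1e-4)

    def test_symmetric_gaussian_hidden_mean(self):
        p = random_params(3, 1, seed=4)
        p.drelu = DReLUParams(np.array([2.0]), np.array([2.0]),
                              np.array([0.0]), np.array([0.0]))
        rng = np.random.default_rng(0)
        codes = np.tile(seqdata.encode("ACG"), (100_000, 1))
        I = rbm.hidden_input(p, codes[:1])[0, 0]
        h = rbm.sample_h_given_s(p, codes, rng)
        assert h.mean() == pytest.approx(I / 2.0, abs=0.02)


class TestAGSSampling:
    def test_uniform_model_gives_uniform_nucleotides(self):
        p = fields_only_params(np.zeros((4, 4)))
        codes = rbm.ags_sample(p, 40_000, n_sweeps=3, n_chains=1000, seed=0,
                               return_codes=True)
        freq = np.bincount(codes.ravel(), minlength=4) / codes.size
        assert np.allclose(freq, 0.25, atol=0.01)

    def test_fixed_seed_reproducible(self, tiny_params):
        a = rbm.ags_sample(tiny_params, 50, n_sweeps=5, n_chains=10, seed=9)
        b = rbm.ags_sample(tiny_params, 50, n_sweeps=5, n_chains=10, seed=9)
        assert a == b

    def test_total_variation_against_enumeration(self, tiny_params):
        codes, probs = enumerate_probs(tiny_params)
        s = rbm.ags_sample(tiny_params, 200_000, n_sweeps=50, n_chains=2000,
                           seed=5, return_codes=True)
        idx = (s[:, 0].astype(int) * 16 + s[:, 1] * 4 + s[:, 2])
        emp = np.bincount(idx, minlength=64) / len(s)
        assert 0.5 * np.abs(emp - probs).sum() < 0.02

    def test_one_sweep_preserves_stationarity(self, tiny_params):
        """One full Gibbs sweep applied to exact-p samples keeps the
        sequence marginal unchanged within Monte-Carlo error."""
        codes, probs = enumerate_probs(tiny_params)
        rng = np.random.default_rng(11)
        n = 200_000
        start = codes[rng.choice(len(codes), p=probs, size=n)]
        h = rbm.sample_h_given_s(tiny_params, start, rng)
        after = rbm.sample_s_given_h(tiny_params, h, rng)
        idx = after[:, 0].astype(int) * 16 + after[:, 1] * 4 + after[:, 2]
        emp = np.bincount(idx, minlength=64) / n
        assert 0.5 * np.abs(emp - probs).sum() < 0.01


class TestDuplicationTrick:
    def test_matches_squared_distribution(self, tiny_params):
        codes, probs = enumerate_probs(tiny_params)
        ull = rbm.unnormalized_log_likelihood(tiny_params, codes)
        p2 = np.exp(2 * ull - logsumexp(2 * ull))
        s = rbm.duplicated_sample(tiny_params, 200_000, n_sweeps=50,
                                  n_chains=2000, seed=6, return_codes=True)
        idx = s[:, 0].astype(int) * 16 + s[:, 1] * 4 + s[:, 2]
        emp = np.bincount(idx, minlength=64) / len(s)
        assert 0.5 * np.abs(emp - p2).sum() < 0.02

    def test_fields_only_equals_doubled_fields(self):
        g = np.random.default_rng(7).normal(0, 0.7, (3, 4))
        p = fields_only_params(g)
        doubled = fields_only_params(2 * g)
        a = rbm.duplicated_sample(p, 5000, n_sweeps=2, n_chains=500, seed=1,
                                  return_codes=True)
        b = rbm.ags_sample(doubled, 5000, n_sweeps=2, n_chains=500, seed=1,
                           return_codes=True)
        # identical conditionals and seed -> identical draws
        assert np.array_equal(a, b)

    def test_sharpening_raises_modal_mass(self, tiny_params):
        codes, probs = enumerate_probs(tiny_params)
        mode = probs.argmax()
        s = rbm.duplicated_sample(tiny_params, 100_000, n_sweeps=40,
                                  n_chains=1000, seed=8, return_codes=True)
        idx = s[:, 0].astype(int) * 16 + s[:, 1] * 4 + s[:, 2]
        emp = np.bincount(idx, minlength=64) / len(s)
        assert emp[mode] > probs[mode]


class TestSerialization:
    def test_archive_roundtrip(self, tiny_params, tmp_path):
        p = tiny_params.copy()
        p.log_Z, p.log_Z_se = 1.23, 0.04
        p.metadata = {"mode": "unique", "seed": 7}
        path = tmp_path / "model.h5"
        rbm.save_params(p, path)
        q = rbm.load_params(path)
        assert np.array_equal(q.g, p.g) and np.array_equal(q.w, p.w)
        assert q.log_Z == p.log_Z and q.metadata == p.metadata
        assert np.array_equal(q.drelu.theta_plus, p.drelu.theta_plus)
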