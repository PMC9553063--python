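"""Enrichment-ratio fits, Fisher ratios, selection strengths,
loop additivity and parasite detection."""

import numpy as np
import pytest
from scipy.stats import norm

from selexrbm import analysis, rbm, seqdata
from selexrbm.analysis import (LLHistogram, additivity_check,
                               bin_loglikelihoods, cross_model_slope,
                               cumulative_betas, enrichment_fit, fisher_ratio,
                               parasite_detect, quadrant_fractions)

from conftest import fields_only_params, random_params


def _hist_from_scores(scores, masses_by_round, n_bins=50):
    edges = np.linspace(scores.min(), scores.max() + 1e-9, n_bins + 1)
    counts = {}
    for r, mass in masses_by_round.items():
        h, _ = np.histogram(scores, bins=edges, weights=mass)
        counts[r] = h
    return LLHistogram(edges, counts)


class TestBinning:
    def test_single_sequence_mass(self):
        g = np.zeros((4, 4))
        params = fields_only_params(g)
        t = seqdata.RoundTable(["ACGT"], np.array([5]), round_index=1)
        hist = bin_loglikelihoods([t], params, n_bins=10)
        assert hist.counts_per_round[1].sum() == 5
        assert (hist.counts_per_round[1] > 0).sum() == 1

    def test_mass_conservation_and_identical_rounds(self, small_table):
        params = fields_only_params(
            np.random.default_rng(0).normal(0, 1, (4, 4)))
        t1 = seqdata.RoundTable(small_table.sequences, small_table.counts,
                                round_index=1)
        t2 = seqdata.RoundTable(small_table.sequences, small_table.counts,
                                round_index=2)
        hist = bin_loglikelihoods([t1, t2], params, n_bins=8)
        for r in (1, 2):
            assert hist.counts_per_round[r].sum() == small_table.total_counts
        assert np.array_equal(hist.counts_per_round[1],
                              hist.counts_per_round[2])


class TestEnrichmentFit:
    def test_identical_rounds_give_zero_slope(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 2, 5000)
        mass = np.ones_like(scores)
        hist = _hist_from_scores(scores, {1: mass, 2: mass})
        fit = enrichment_fit(hist, (1, 2), window=(-np.inf, np.inf))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.log_enrichment, 0.0)

    @pytest.mark.parametrize("alpha", [0.2, 0.5])
    def test_exact_reweighting_recovers_alpha(self, alpha):
        """Population reweighted by exp(alpha * score): the fitted slope
        converges to alpha as bins narrow (monotone over 3 widths)."""
        rng = np.random.default_rng(2)
        scores = rng.normal(0, 1.5, 200_000)
        q0 = np.ones_like(scores)
        q1 = np.exp(alpha * scores)
        errs = []
        for n_bins in (10, 40, 160):
            hist = _hist_from_scores(scores, {0: q0, 1: q1}, n_bins=n_bins)
            fit = enrichment_fit(hist, (0, 1), window=(-np.inf, np.inf))
            errs.append(abs(fit.slope - alpha))
        assert errs[-1] < 0.1 * alpha
        assert errs[2] <= errs[0] + 1e-9

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 1, 20_000)
        q1 = np.exp(0.3 * scores)
        h1 = _hist_from_scores(scores, {0: np.ones_like(scores), 1: q1})
        h2 = _hist_from_scores(scores + 57.0,
                               {0: np.ones_like(scores), 1: q1})
        f1 = enrichment_fit(h1, (0, 1), window=(-np.inf, np.inf))
        f2 = enrichment_fit(h2, (0, 1), window=(-np.inf, np.inf))
        assert f1.slope == pytest.approx(f2.slope, rel=1e-9)

    def test_too_few_bins_rejected(self):
        hist = LLHistogram(np.array([0.0, 1.0, 2.0]),
                           {0: np.array([1.0, 0.0]), 1: np.array([1.0, 0.0])})
        with pytest.raises(ValueError, match="3 usable bins"):
            enrichment_fit(hist, (0, 1), window=(-np.inf, np.inf))


class TestFisherRatio:
    def test_identical_distributions_zero(self):
        x = np.random.default_rng(0).normal(size=1000)
        assert fisher_ratio(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_tilt_recovers_alpha(self):
        """Exponential tilt of a Gaussian shifts the mean by alpha*var."""
        alpha = 0.3
        x = np.random.default_rng(1).normal(0, 1, 500_000)
        w_next = np.exp(alpha * x)
        got = fisher_ratio(x, x, weights_prev=None, weights_next=w_next)
        assert got == pytest.approx(alpha, rel=0.03)

    def test_matches_regression_slope_in_gaussian_limit(self):
        """Closed-form check on a fine deterministic Gaussian grid."""
        alpha = 0.25
        grid = np.linspace(-6, 6, 4001)
        q0 = norm.pdf(grid)
        q1 = q0 * np.exp(alpha * grid)
        fr = fisher_ratio(grid, grid, weights_prev=q0, weights_next=q1)
        hist = _hist_from_scores(grid, {0: q0, 1: q1}, n_bins=400)
        fit = enrichment_fit(hist, (0, 1), window=(-4, 4))
        assert fr == pytest.approx(alpha, rel=0.01)
        assert fit.slope == pytest.approx(fr, rel=0.02)

    def test_count_splitting_invariance(self):
        scores = np.array([1.0, 2.0, 5.0])
        counts_prev = np.array([3, 2, 1])
        counts_next = np.array([1, 2, 3])
        a = fisher_ratio(scores, scores, counts_prev, counts_next)
        split_prev = np.repeat(scores, counts_prev)
        split_next = np.repeat(scores, counts_next)
        b = fisher_ratio(split_prev, split_next)
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fisher_ratio(np.ones(5), np.zeros(5))


class TestSelectionStrengths:
    def test_direct_product(self):
        s = cumulative_betas({(6, 7): 1.2, (7, 8): 1.1}, reference_round=6)
        assert s.betas[6] == pytest.approx(1.0)
        assert s.betas[7] == pytest.approx(1.2)
        assert s.betas[8] == pytest.approx(1.32)
        assert s.alphas[6] == pytest.approx(0.2)
        assert s.alphas[7] == pytest.approx(0.12)

    def test_consistent_overdetermined_input(self):
        s = cumulative_betas({(5, 6): 2.0, (6, 7): 1.5, (5, 7): 3.0},
                             reference_round=5)
        assert s.betas[7] == pytest.approx(3.0, rel=1e-9)

    def test_disconnected_graph_rejected(self):
        with pytest.raises(ValueError, match="disconnected"):
            cumulative_betas({(5, 6): 2.0, (8, 9): 1.5}, reference_round=5)


class TestCrossModelSlope:
    def test_identity_model(self, small_table):
        p = fields_only_params(
            np.random.default_rng(0).normal(0, 1, (4, 4)))
        slope, r2 = cross_model_slope(p, p, small_table)
        assert slope == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_scaled_fields_give_scaled_slope(self, small_table):
        g = np.random.default_rng(1).normal(0, 1, (4, 4))
        slope, r2 = cross_model_slope(
            fields_only_params(g), fields_only_params(2 * g), small_table)
        assert slope == pytest.approx(2.0, rel=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_unrelated_models_weak_correlation(self):
        rng = np.random.default_rng(2)
        seqs = list({s: None for s in
                     ("".join(rng.choice(list("ACGT"), 12))
                      for _ in range(400))})
        table = seqdata.RoundTable.from_records((s, 1) for s in seqs)
        pa = random_params(12, 2, seed=10)
        pb = random_params(12, 2, seed=20)
        _, r2 = cross_model_slope(pa, pb, table)
        assert r2 < 0.3


class TestAdditivity:
    def test_exact_for_independent_loop_copies(self):
        g = np.random.default_rng(0).normal(0, 1, (20, 4))
        single = fields_only_params(g)
        double = fields_only_params(np.vstack([g, g]))
        rng = np.random.default_rng(1)
        seqs = list({s: None for s in
                     ("".join(rng.choice(list("ACGT"), 40))
                      for _ in range(200))})
        table = seqdata.RoundTable.from_records((s, 1) for s in seqs)
        slope, r2 = additivity_check(double, single, table)
        assert slope == pytest.approx(1.0, rel=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_shape_validation(self, small_table):
        p20 = fields_only_params(np.zeros((20, 4)))
        with pytest.raises(ValueError):
            additivity_check(p20, p20, small_table)


class TestQuadrants:
    def test_all_in_region_one(self):
        f = quadrant_fractions(np.array([2.0, 3.0]), np.array([2.0, 5.0]),
                               thresholds=(0.0, 0.0))
        assert f == {"I": 1.0, "II": 0.0, "III": 0.0, "IV": 0.0}

    def test_fractions_sum_to_one_and_symmetric_cloud(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=100_000), rng.normal(size=100_000)
        f = quadrant_fractions(x, y, thresholds=(0.0, 0.0))
        assert sum(f.values()) == pytest.approx(1.0)
        for v in f.values():
            assert v == pytest.approx(0.25, abs=0.01)

    def test_count_weighting(self):
        f = quadrant_fractions(np.array([1.0, -1.0]), np.array([1.0, -1.0]),
                               thresholds=(0.0, 0.0),
                               weights=np.array([3.0, 1.0]))
        assert f["I"] == pytest.approx(0.75) and f["III"] == pytest.approx(0.25)


class TestParasites:
    def _motif_model(self):
        # strong fields favouring one specific 20-mer
        g = np.full((20, 4), -1.0)
        motif = seqdata.encode("G" * 5 + "T" * 5 + "G" * 5 + "T" * 5)[0]
        g[np.arange(20), motif] = 1.0
        return fields_only_params(g), "G" * 5 + "T" * 5 + "G" * 5 + "T" * 5

    def test_constructed_parasite_flagged(self):
        params, good = self._motif_model()
        rng = np.random.default_rng(0)
        rand_loop = "".join(rng.choice(list("ACGT"), 20))
        table = seqdata.RoundTable([good + rand_loop], np.array([1]))
        frame, thr = parasite_detect(params, table, n_random=20_000, seed=1)
        assert len(frame) == 1
        assert frame.iloc[0]["side"] == "right"
        assert frame.iloc[0]["parasite_loop"] == rand_loop

    def test_double_low_aptamer_not_flagged(self):
        params, good = self._motif_model()
        rng = np.random.default_rng(2)
        both_low = "".join(rng.choice(list("ACGT"), 40))
        table = seqdata.RoundTable([both_low], np.array([1]))
        frame, _ = parasite_detect(params, table, n_random=20_000, seed=1)
        assert frame.empty

    def test_reproducible_threshold(self):
        params, good = self._motif_model()
        t1 = analysis.random_sequence_threshold(params, 20_000, seed=3)
        t2 = analysis.random_sequence_threshold(params, 20_000, seed=3)
        assert t1 == t2

    def test_small_n_random_warns(self):
        params, _ = self._motif_model()
        with pytest.warns(UserWarning):
            analysis.random_sequence_threshold(params, n_random=500, seed=0)
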