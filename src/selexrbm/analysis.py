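"""Selection-dynamics analysis: enrichment ratios, selection strengths,
loop additivity and parasite loops.

Under exponential selection, the frequency of sequence s evolves between
consecutive rounds as q_r(s) ~ exp(alpha_{r-1} F(s)) q_{r-1}(s), so the
log of the enrichment ratio is linear in the fitness F with slope
alpha_{r-1}.  Because per-sequence enrichment ratios are hopelessly
subsampled at realistic depths, sequences are pooled into bins of similar
model log-likelihood (the fitness proxy) and the *effective* enrichment
ratio E_r(bin) = C_r(bin) / C_{r-1}(bin) of cumulative counts is
regressed on the bin log-likelihood.  Fisher's fundamental theorem gives
an independent estimate of the same selection strength:
alpha = (mean_r - mean_{r-1}) / var_{r-1} of the fitness proxy.
Cumulative strengths beta_r = alpha_0 + ... + alpha_{r-1} act as the
effective inverse temperature of the round-r sequence distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from . import rbm, seqdata


@dataclass
class LLHistogram:
    """Per-round cumulative counts over common log-likelihood bins."""

    bin_edges: np.ndarray
    counts_per_round: dict  # round index -> (n_bins,) count-mass array

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class EnrichmentFit:
    round_pair: tuple
    bin_centers: np.ndarray
    log_enrichment: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    fit_window: tuple
    excluded_mass_fraction: float


@dataclass
class SelectionStrengths:
    betas: dict          # round -> beta_r (units of beta at the reference)
    alphas: dict         # round -> alpha_r = beta_{r+1} - beta_r
    reference_round: int
    fisher_ratios: dict | None = None


def bin_loglikelihoods(tables: list[seqdata.RoundTable],
                       params: rbm.RBMParams, n_bins: int = 100,
                       weighted: bool = True) -> LLHistogram:
    """Histogram the model log-likelihoods of several rounds on shared bins.

    Bin masses are read counts (``weighted=True``) or unique-sequence
    counts; edges span the pooled min/max across all rounds.
    """
    if not tables:
        raise ValueError("no round tables given")
    lls = [rbm.unnormalized_log_likelihood(params, t.codes) for t in tables]
    lo = min(ll.min() for ll in lls)
    hi = max(ll.max() for ll in lls)
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    counts = {}
    for t, ll in zip(tables, lls):
        w = t.counts.astype(float) if weighted else None
        hist, _ = np.histogram(ll, bins=edges, weights=w)
        key = t.round_index if t.round_index is not None else len(counts)
        counts[key] = hist
    return LLHistogram(edges, counts)


def enrichment_fit(hist: LLHistogram, round_pair: tuple,
                   window: tuple | None = None,
                   min_mass_fraction: float | None = 0.005) -> EnrichmentFit:
    """Regress per-bin log enrichment ratios on bin log-likelihood.

    Parameters
    ----------
    round_pair : (r_prev, r_next)
        Keys into ``hist.counts_per_round``.
    window : (ll_min, ll_max), optional
        Only bins with centers inside the window enter the fit.  When
        omitted, a window excluding the under-sampled tails holding
        ``min_mass_fraction`` of the pooled count mass is used.
    """
    r_prev, r_next = round_pair
    try:
        c_prev = hist.counts_per_round[r_prev].astype(float)
        c_next = hist.counts_per_round[r_next].astype(float)
    except KeyError as exc:
        raise ValueError(f"round {exc} not present in histogram") from exc
    centers = hist.bin_centers
    total = c_prev + c_next

    if window is None:
        if min_mass_fraction:
            cum = np.cumsum(total) / total.sum()
            lo_i = int(np.searchsorted(cum, min_mass_fraction / 2))
            hi_i = int(np.searchsorted(cum, 1 - min_mass_fraction / 2))
            hi_i = max(hi_i, lo_i + 1)
            window = (float(hist.bin_edges[lo_i]),
                      float(hist.bin_edges[min(hi_i + 1, len(centers))]))
        else:
            window = (-np.inf, np.inf)

    usable = (c_prev > 0) & (c_next > 0) & \
        (centers >= window[0]) & (centers <= window[1])
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable bins for the enrichment fit")
    log_e = np.log(c_next[usable] / c_prev[usable])
    x = centers[usable]
    res = stats.linregress(x, log_e)
    excluded = float(total[~usable].sum() / total.sum())
    return EnrichmentFit(
        round_pair=round_pair, bin_centers=x, log_enrichment=log_e,
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), fit_window=window,
        excluded_mass_fraction=excluded)


def fisher_ratio(ll_prev: np.ndarray, ll_next: np.ndarray,
                 weights_prev: np.ndarray | None = None,
                 weights_next: np.ndarray | None = None,
                 variance_round: str = "prev") -> float:
    """Selection strength via Fisher's fundamental theorem.

    (mean_next - mean_prev) / var of the fitness proxy (log-likelihood),
    count-weighted.  ``variance_round`` selects which round's variance to
    divide by; 'prev' (pre-selection) is the theorem-consistent choice.
    """
    ll_prev = np.asarray(ll_prev, float)
    ll_next = np.asarray(ll_next, float)
    if len(ll_prev) == 0 or len(ll_next) == 0:
        raise ValueError("empty score vectors")
    m_prev = np.average(ll_prev, weights=weights_prev)
    m_next = np.average(ll_next, weights=weights_next)
    if variance_round == "prev":
        var = np.average((ll_prev - m_prev)**2, weights=weights_prev)
    elif variance_round == "next":
        var = np.average((ll_next - m_next)**2, weights=weights_next)
    else:
        raise ValueError("variance_round must be 'prev' or 'next'")
    if var <= 0:
        raise ValueError("zero variance in the fitness proxy")
    return float((m_next - m_prev) / var)


def cross_model_slope(params_a: rbm.RBMParams, params_b: rbm.RBMParams,
                      eval_table: seqdata.RoundTable) -> tuple[float, float]:
    """Least-squares slope (and R^2) of log p_b vs log p_a on unique
    sequences; the slope estimates the ratio of cumulative selection
    strengths beta_b / beta_a of the two training rounds."""
    if params_a.L != params_b.L:
        raise ValueError("models have different sequence lengths")
    if eval_table.n_unique == 0:
        raise ValueError("empty evaluation table")
    x = rbm.unnormalized_log_likelihood(params_a, eval_table.codes)
    y = rbm.unnormalized_log_likelihood(params_b, eval_table.codes)
    if np.var(x) == 0:
        raise ValueError("degenerate variance in reference scores")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def cumulative_betas(slopes: dict, reference_round: int) -> SelectionStrengths:
    """Least-squares-consistent beta_r from pairwise ratios.

    ``slopes[(r, r2)]`` is an estimate of beta_r2 / beta_r (e.g. a
    cross-model regression slope).  Solved in the log domain with
    beta at the reference round fixed to 1.
    """
    rounds = sorted({r for pair in slopes for r in pair})
    if reference_round not in rounds:
        rounds.append(reference_round)
        rounds.sort()
    graph = nx.Graph()
    graph.add_nodes_from(rounds)
    graph.add_edges_from(slopes.keys())
    if not nx.is_connected(graph):
        raise ValueError("round-pair graph is disconnected")
    index = {r: i for i, r in enumerate(rounds)}
    rows, rhs = [], []
    for (r, r2), ratio in slopes.items():
        if ratio <= 0:
            raise ValueError(f"non-positive slope for pair {(r, r2)}")
        row = np.zeros(len(rounds))
        row[index[r2]], row[index[r]] = 1.0, -1.0
        rows.append(row)
        rhs.append(np.log(ratio))
    # anchor the reference round
    row = np.zeros(len(rounds))
    row[index[reference_round]] = 1.0
    rows.append(row)
    rhs.append(0.0)
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    betas = {r: float(np.exp(sol[index[r]])) for r in rounds}
    alphas = {r: betas[r2] - betas[r]
              for r, r2 in zip(rounds[:-1], rounds[1:])}
    return SelectionStrengths(betas=betas, alphas=alphas,
                              reference_round=reference_round)


# -- double-loop structure ------------------------------------------------

def additivity_check(params_double: rbm.RBMParams,
                     params_single: rbm.RBMParams,
                     eval_table: seqdata.RoundTable) -> tuple[float, float]:
    """Regress double-loop scores on the sum of single-loop scores.

    A slope near 1 (up to normalization) with high R^2 indicates the two
    loops contribute additively to the full-aptamer log-likelihood.
    """
    if params_double.L != 40 or params_single.L != 20:
        raise ValueError("need a 40-nt double model and a 20-nt single model")
    if eval_table.L != 40:
        raise ValueError("evaluation table must hold 40-nt sequences")
    codes = eval_table.codes
    ll_double = rbm.unnormalized_log_likelihood(params_double, codes)
    ll_left = rbm.unnormalized_log_likelihood(params_single, codes[:, :20])
    ll_right = rbm.unnormalized_log_likelihood(params_single, codes[:, 20:])
    x = ll_left + ll_right
    if np.var(x) == 0:
        raise ValueError("degenerate variance in single-loop score sums")
    res = stats.linregress(x, ll_double)
    return float(res.slope), float(res.rvalue**2)


def quadrant_fractions(ll_left: np.ndarray, ll_right: np.ndarray,
                       thresholds: tuple,
                       weights: np.ndarray | None = None) -> dict:
    """Count-weighted fractions of aptamers in the four (left, right)
    score quadrants: I = both high, II = left high only, III = both low,
    IV = right high only.  Scores at a threshold count as high."""
    ll_left = np.asarray(ll_left, float)
    ll_right = np.asarray(ll_right, float)
    t_l, t_r = thresholds
    if weights is None:
        weights = np.ones_like(ll_left)
    weights = np.asarray(weights, float)
    hi_l, hi_r = ll_left >= t_l, ll_right >= t_r
    total = weights.sum()
    return {
        "I": float(weights[hi_l & hi_r].sum() / total),
        "II": float(weights[hi_l & ~hi_r].sum() / total),
        "III": float(weights[~hi_l & ~hi_r].sum() / total),
        "IV": float(weights[~hi_l & hi_r].sum() / total),
    }


def random_sequence_threshold(params_single: rbm.RBMParams,
                              n_random: int = 100000, quantile: float = 0.99,
                              seed: int = 0) -> float:
    """Score quantile of uniformly random sequences under a single-loop
    model; used as the 'looks selected' cutoff for parasite calling."""
    import warnings
    if n_random < 1000:
        warnings.warn("n_random < 1000: the quantile threshold will be noisy")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n_random, params_single.L)).astype(np.int8)
    ll = rbm.unnormalized_log_likelihood(params_single, codes)
    return float(np.quantile(ll, quantile))


def parasite_detect(params_single: rbm.RBMParams,
                    table: seqdata.RoundTable, n_random: int = 100000,
                    quantile: float = 0.99, seed: int = 0):
    """Flag parasite loops in a table of 40-nt double-loop aptamers.

    A loop is a parasite when its own score falls below the
    random-sequence quantile threshold while its partner loop scores at
    or above it — i.e. it rides through selection on its partner's
    binding.  Returns (DataFrame of flagged loops, threshold).
    """
    import pandas as pd
    if table.L != 40:
        raise ValueError("parasite detection needs 40-nt aptamers")
    thr = random_sequence_threshold(params_single, n_random, quantile, seed)
    codes = table.codes
    ll_left = rbm.unnormalized_log_likelihood(params_single, codes[:, :20])
    ll_right = rbm.unnormalized_log_likelihood(params_single, codes[:, 20:])
    rows = []
    for i, seq in enumerate(table.sequences):
        left_low, right_low = ll_left[i] < thr, ll_right[i] < thr
        if left_low and not right_low:
            rows.append((seq[:20], "left", seq, float(ll_left[i]),
                         float(ll_right[i]), int(table.counts[i])))
        elif right_low and not left_low:
            rows.append((seq[20:], "right", seq, float(ll_right[i]),
                         float(ll_left[i]), int(table.counts[i])))
    frame = pd.DataFrame(rows, columns=[
        "parasite_loop", "side", "aptamer", "parasite_ll", "partner_ll",
        "count"])
    return frame, thr
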