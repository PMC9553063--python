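"""Binder prediction and sequence design.

Covers the decision pipeline used to propose new aptamers: calibrate a
binder/non-binder log-likelihood threshold on labelled sequences, score
and classify candidates, generate novel sequences by Gibbs sampling from
p(s) or p(s)^2, search for minimal disruptive mutations, and mine the
dataset for count/likelihood mismatches.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import rbm, seqdata


@dataclass(frozen=True)
class BindingThreshold:
    """Calibrated score cut: predict binder iff score >= value."""

    value: float
    n_errors: int
    interval: tuple
    calibration_hash: str


def _misclassification_curve(scores: np.ndarray, labels: np.ndarray):
    """Errors of the rule (score >= t -> binder) per threshold region.

    Regions are delimited by the distinct sorted scores d_0 < ... <
    d_{m-1}: region 0 is t <= d_0 (everything predicted binder), region
    j in 1..m-1 is d_{j-1} < t <= d_j, region m is t > d_{m-1}.
    """
    d = np.unique(scores)
    errors = []
    for j in range(len(d) + 1):
        t = -np.inf if j == 0 else d[j - 1] + 0.0
        if j == 0:
            pred = np.ones_like(labels, dtype=bool)
        elif j == len(d):
            pred = np.zeros_like(labels, dtype=bool)
        else:
            pred = scores > d[j - 1]
        errors.append(int(np.sum(pred != labels)))
    return d, np.array(errors)


def calibrate_threshold(scores, labels) -> BindingThreshold:
    """Choose the score threshold minimizing misclassifications.

    ``labels`` are booleans (True = binder).  The minimizing thresholds
    form one or more intervals between consecutive distinct scores; the
    midpoint (median) of the lowest optimal interval is returned.
    Unbounded optimal ends are clamped one unit beyond the extreme score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("calibration needs both binders and non-binders")
    d, errors = _misclassification_curve(scores, labels)
    best = errors.min()
    optimal = np.flatnonzero(errors == best)
    # group consecutive optimal regions; keep the lowest group
    first = [optimal[0]]
    for j in optimal[1:]:
        if j == first[-1] + 1:
            first.append(j)
        else:
            break
    lo_region, hi_region = first[0], first[-1]
    lo = d[0] - 1.0 if lo_region == 0 else float(d[lo_region - 1])
    hi = d[-1] + 1.0 if hi_region == len(d) else float(d[hi_region])
    value = 0.5 * (lo + hi)
    digest = hashlib.md5(
        repr(sorted(zip(scores.tolist(), labels.tolist()))).encode()
    ).hexdigest()[:12]
    return BindingThreshold(value=float(value), n_errors=int(best),
                            interval=(lo, hi), calibration_hash=digest)


def predict_binding(scores, threshold) -> np.ndarray:
    """'B' iff score >= threshold (inclusive at the boundary), else 'NB'."""
    t = threshold.value if isinstance(threshold, BindingThreshold) else \
        float(threshold)
    scores = np.atleast_1d(np.asarray(scores, dtype=float))
    return np.where(scores >= t, "B", "NB")


def roc_auc(scores, labels) -> float:
    """Probability a random binder outscores a random non-binder
    (Mann-Whitney formulation; ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


# -- candidate generation -------------------------------------------------

def generate_candidates(params: rbm.RBMParams, threshold,
                        dataset: seqdata.RoundTable, n: int = 4000,
                        use_duplication: bool = False, min_distance: int = 0,
                        seed: int = 0, n_sweeps: int = 100,
                        n_chains: int = 100) -> pd.DataFrame:
    """Sample candidate binders and annotate them against the dataset.

    Sequences are drawn from p(s) (or p(s)^2 with ``use_duplication``),
    de-duplicated, scored, annotated with the minimum Hamming distance to
    the dataset, filtered to score >= threshold and distance >=
    ``min_distance``, and sorted by score descending.
    """
    sampler = rbm.duplicated_sample if use_duplication else rbm.ags_sample
    codes = sampler(params, n, n_sweeps=n_sweeps, n_chains=n_chains,
                    seed=seed, return_codes=True)
    seqs = seqdata.decode(codes)
    uniq_idx = sorted({s: i for i, s in enumerate(seqs)}.values())
    codes = codes[uniq_idx]
    ll = rbm.unnormalized_log_likelihood(params, codes)
    dist = seqdata.distances_to_set(codes, dataset)
    t = threshold.value if isinstance(threshold, BindingThreshold) else \
        float(threshold)
    frame = pd.DataFrame({
        "sequence": seqdata.decode(codes),
        "log_likelihood": ll,
        "prediction": np.where(ll >= t, "B", "NB"),
        "min_distance_to_dataset": dist,
        "provenance": "sampled_p2" if use_duplication else "sampled_p",
    })
    keep = (frame["log_likelihood"] >= t) & \
        (frame["min_distance_to_dataset"] >= min_distance)
    out = frame[keep].sort_values(
        ["log_likelihood", "sequence"], ascending=[False, True],
        kind="stable").reset_index(drop=True)
    if out.empty:
        warnings.warn("no candidates survived the threshold/distance filter")
    return out


def no_g_removal(pos: int, old: str, new: str) -> bool:
    """Mutation constraint: forbid mutating away an existing G."""
    return old != "G"


def critical_mutation_search(params: rbm.RBMParams, s0: str, k: int = 1,
                             constraint=None,
                             max_enumeration: int = 2_000_000) -> pd.DataFrame:
    """Exhaustive search for the <= k mutations that most decrease the score.

    Enumerates every mutant of ``s0`` with 1..k substituted sites (all
    3 alternatives per site), optionally restricted by ``constraint(pos,
    old, new)`` (1-based position), and ranks mutants by ascending
    log-likelihood, reporting the drop relative to ``s0``.
    """
    L = len(s0)
    total = sum(
        int(np.prod([L - j for j in range(kk)]) / np.prod(range(1, kk + 1)))
        * 3**kk for kk in range(1, k + 1))
    if total > max_enumeration:
        raise ValueError(
            f"{total} mutants exceed the enumeration budget; reduce k")
    alphabet = seqdata.ALPHABET
    mutants, muts = [], []
    for kk in range(1, k + 1):
        for positions in itertools.combinations(range(L), kk):
            alts = []
            for p in positions:
                choices = [c for c in alphabet if c != s0[p]
                           and (constraint is None
                                or constraint(p + 1, s0[p], c))]
                alts.append(choices)
            for combo in itertools.product(*alts):
                seq = list(s0)
                for p, c in zip(positions, combo):
                    seq[p] = c
                mutants.append("".join(seq))
                muts.append(tuple(
                    f"{s0[p]}{p + 1}{c}" for p, c in zip(positions, combo)))
    if not mutants:
        return pd.DataFrame(columns=[
            "sequence", "mutations", "n_mutations", "log_likelihood",
            "ll_drop"])
    ll0 = float(params.score(s0)[0])
    ll = params.score(mutants)
    frame = pd.DataFrame({
        "sequence": mutants,
        "mutations": muts,
        "n_mutations": [len(m) for m in muts],
        "log_likelihood": ll,
        "ll_drop": ll - ll0,
    })
    return frame.sort_values(
        ["log_likelihood", "sequence"], kind="stable").reset_index(drop=True)


def mismatch_mining(params: rbm.RBMParams, table: seqdata.RoundTable,
                    high_count_min: int = 139,
                    low_count_max: int = 11) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mine count/likelihood mismatches.

    Returns two ranked tables: (1) high-count sequences (count >=
    ``high_count_min``) sorted by ascending score — popular sequences the
    model dislikes; (2) low-count sequences (count <= ``low_count_max``)
    sorted by descending score — rare sequences the model favours.
    Default cutoffs follow the reference analysis (139 and 11 counts).
    """
    ll = rbm.unnormalized_log_likelihood(params, table.codes)
    frame = pd.DataFrame({
        "sequence": table.sequences,
        "count": table.counts,
        "log_likelihood": ll,
    })
    high = frame[frame["count"] >= high_count_min].sort_values(
        ["log_likelihood", "sequence"], ascending=[True, True],
        kind="stable").reset_index(drop=True)
    low = frame[frame["count"] <= low_count_max].sort_values(
        ["log_likelihood", "sequence"], ascending=[False, True],
        kind="stable").reset_index(drop=True)
    return high, low
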