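"""Sequencing-error-rate estimation from spurious single-mutant reads.

A read of a high-count "peak" sequence that suffers exactly one
sequencing error shows up as a low-count sequence one mutation away from
the peak.  Comparing the expected mass of such single-error reads with
the mass actually observed among the peaks' one-mutant neighbours gives
an estimate of the per-nucleotide error probability epsilon.  Neighbours
with genuinely high fitness inflate the observed mass, so the estimate
is an upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import seqdata


@dataclass
class ErrorEstimate:
    epsilon_upper: float
    n_peaks_used: int
    observed_neighbor_mass: int
    expected_neighbor_mass_at_epsilon: float
    n_spurious_expected: float


def _one_mutant_neighbors(seq: str):
    for i, old in enumerate(seq):
        for c in seqdata.ALPHABET:
            if c != old:
                yield seq[:i] + c + seq[i + 1:]


def _expected_single_error_mass(peak_counts: np.ndarray, L: int,
                                eps: float) -> float:
    """Expected reads carrying exactly one error, summed over peaks:
    C * L * eps * (1 - eps)^(L-1)."""
    return float(peak_counts.sum() * L * eps * (1.0 - eps) ** (L - 1))


def estimate_error_rate(table: seqdata.RoundTable,
                        peak_count_min: int = 1000,
                        neighbor_count_max: int = 10) -> ErrorEstimate:
    """Estimate the per-nucleotide sequencing error rate (upper bound).

    Peaks are sequences with count >= ``peak_count_min``.  The observed
    mass is the total count of their one-mutant neighbours with count <=
    ``neighbor_count_max`` (neighbours that are themselves peaks are
    excluded: they may be genuinely selected variants).  epsilon solves
    expected-single-error-reads(epsilon) = observed mass.
    """
    L = table.L
    peak_mask = table.counts >= peak_count_min
    if not peak_mask.any():
        raise ValueError(f"no peak sequences with count >= {peak_count_min}")
    peak_seqs = [s for s, m in zip(table.sequences, peak_mask) if m]
    peak_counts = table.counts[peak_mask]
    peak_set = set(peak_seqs)

    observed = 0
    seen = set()
    for peak in peak_seqs:
        for nb in _one_mutant_neighbors(peak):
            if nb in peak_set or nb in seen:
                continue
            seen.add(nb)
            c = table.count_of(nb)
            if 1 <= c <= neighbor_count_max:
                observed += c

    if observed == 0:
        eps = 0.0
    else:
        f = lambda e: _expected_single_error_mass(peak_counts, L, e) - observed
        # expected mass grows with eps only up to eps = 1/L; solve on the
        # monotone branch (the physically relevant small-eps root)
        hi = 1.0 / L
        if f(hi) < 0:  # more neighbour mass than errors can explain
            eps = hi
        else:
            eps = float(brentq(f, 0.0, hi, xtol=1e-12))
    n_spurious = expected_spurious_uniques(table, eps)
    return ErrorEstimate(
        epsilon_upper=eps,
        n_peaks_used=int(peak_mask.sum()),
        observed_neighbor_mass=int(observed),
        expected_neighbor_mass_at_epsilon=_expected_single_error_mass(
            peak_counts, L, eps),
        n_spurious_expected=n_spurious)


def expected_spurious_uniques(table: seqdata.RoundTable,
                              epsilon: float) -> float:
    """Expected number of distinct error-generated neighbour sequences.

    Each sequence with count C sends about C * L * epsilon single-error
    reads uniformly over its 3L one-mutant neighbours; a neighbour is a
    new unique sequence once at least one such read hits it, giving
    3L * (1 - exp(-C L eps / (3L))) per source sequence.  Neighbours that
    coincide with real records are not discounted (small correction).
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    L = table.L
    rate = table.counts.astype(float) * L * epsilon / (3.0 * L)
    return float(np.sum(3.0 * L * (-np.expm1(-rate))))
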