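"""Model introspection: weight norms, logo matrices, hidden-unit
projections and per-position importance profiles.

All outputs are pure functions of the parameter arrays (no randomness).
Logo rendering itself is left to external plotting; the matrices exported
here are the heights (positive above the axis, negative below).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import rbm, seqdata


def frobenius_norms(params: rbm.RBMParams) -> pd.DataFrame:
    """Per-unit Frobenius norms, sorted descending (ties by unit index).

    For 40-nt double-loop models the norm is also decomposed into the
    left (sites 1-20) and right (sites 21-40) contributions, with
    norm^2 = left^2 + right^2 exactly.
    """
    w = params.w
    norms = np.sqrt((w**2).sum(axis=(1, 2)))
    data = {"unit": np.arange(params.M), "frobenius_norm": norms}
    if params.L == 40:
        data["left_norm"] = np.sqrt((w[:, :20, :]**2).sum(axis=(1, 2)))
        data["right_norm"] = np.sqrt((w[:, 20:, :]**2).sum(axis=(1, 2)))
    frame = pd.DataFrame(data)
    frame = frame.sort_values(
        ["frobenius_norm", "unit"], ascending=[False, True],
        kind="stable").reset_index(drop=True)
    frame["rank"] = np.arange(len(frame))
    return frame


def weight_logo_matrix(params: rbm.RBMParams, unit: int) -> pd.DataFrame:
    """The (L, 4) weight matrix of one hidden unit, 1-based positions."""
    if not 0 <= unit < params.M:
        raise ValueError(f"unit {unit} out of range [0, {params.M})")
    frame = pd.DataFrame(params.w[unit], columns=list(seqdata.ALPHABET))
    frame.index = np.arange(1, params.L + 1)
    frame.index.name = "position"
    return frame


def hidden_input_projection(params: rbm.RBMParams,
                            table: seqdata.RoundTable,
                            units: list[int]) -> pd.DataFrame:
    """Per-sequence coordinates I_mu(s) for the selected units.

    Useful for scatter plots and clustering: sequence families separate
    in the subspace spanned by the strongest units' inputs.
    """
    for u in units:
        if not 0 <= u < params.M:
            raise ValueError(f"unit {u} out of range [0, {params.M})")
    I = rbm.hidden_input(params, table.codes)
    frame = pd.DataFrame({f"I_{u}": I[:, u] for u in units})
    frame.insert(0, "sequence", table.sequences)
    return frame


def position_importance(params: rbm.RBMParams) -> np.ndarray:
    """Per-site sum over units of the site's weight norm:
    profile_i = sum_mu sqrt(sum_a w_mu,i(a)^2)."""
    if params.M == 0:
        return np.zeros(params.L)
    return np.sqrt((params.w**2).sum(axis=2)).sum(axis=0)
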