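"""RBM probability model over fixed-length DNA sequences.

The joint distribution over a sequence s (L categorical sites over
A/C/G/T) and M real hidden units h is

    p(s, h) = exp( sum_i g_i(s_i) - sum_mu U_mu(h_mu)
                   + sum_mu h_mu I_mu(s) ) / Z,
    I_mu(s) = sum_i w_mu,i(s_i),

with dReLU potentials U_mu (see :mod:`selexrbm.drelu`).  Marginalizing the
hidden layer is analytic, giving the sequence score

    log ptilde(s) = sum_i g_i(s_i) + sum_mu Gamma_mu(I_mu(s)),

so that log p(s) = log ptilde(s) - log Z.  Score *differences* between
sequences never involve Z; the absolute normalization is estimated by
annealed importance sampling when needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.special import logsumexp

from . import seqdata
from .drelu import DReLUParams, log_partition, mean_activity, sample_hidden

_ARCHIVE_VERSION = 1


@dataclass
class RBMParams:
    """Trained (or hand-built) RBM parameters.

    Attributes
    ----------
    g : (L, 4) array
        Visible fields g_i(a).
    w : (M, L, 4) array
        Weights w_mu,i(a); M may be 0 for an independent-site model.
    drelu : DReLUParams
        Hidden-unit potential parameters, one set per unit.
    log_Z : float or None
        Estimated log normalization (with ``log_Z_se``); ``None`` until
        :func:`estimate_log_Z` is run.
    """

    g: np.ndarray
    w: np.ndarray
    drelu: DReLUParams
    log_Z: float | None = None
    log_Z_se: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.g.ndim != 2 or self.g.shape[1] != 4:
            raise ValueError("g must have shape (L, 4)")
        if self.w.ndim != 3 or self.w.shape[1:] != self.g.shape:
            raise ValueError("w must have shape (M, L, 4)")
        if self.drelu.M != self.w.shape[0]:
            raise ValueError("drelu parameter count does not match M")
        if not (np.isfinite(self.g).all() and np.isfinite(self.w).all()):
            raise ValueError("non-finite model parameters")

    @property
    def L(self) -> int:
        return self.g.shape[0]

    @property
    def M(self) -> int:
        return self.w.shape[0]

    def copy(self) -> "RBMParams":
        return RBMParams(
            self.g.copy(), self.w.copy(),
            DReLUParams(self.drelu.gamma_plus.copy(),
                        self.drelu.gamma_minus.copy(),
                        self.drelu.theta_plus.copy(),
                        self.drelu.theta_minus.copy()),
            self.log_Z, self.log_Z_se, dict(self.metadata))

    # convenience wrappers -------------------------------------------------
    def score(self, sequences) -> np.ndarray:
        """Unnormalized log-likelihood of sequences (str or codes)."""
        codes = _as_codes(sequences, self.L)
        return unnormalized_log_likelihood(self, codes)


def _as_codes(sequences, L: int) -> np.ndarray:
    if isinstance(sequences, np.ndarray) and sequences.dtype != object:
        codes = np.atleast_2d(sequences)
    else:
        codes = seqdata.encode(sequences)
    if codes.shape[1] != L:
        raise ValueError(f"sequence length {codes.shape[1]} != model L={L}")
    return codes


def hidden_input(params: RBMParams, sequences, block: int = 65536) -> np.ndarray:
    """Inputs I_mu(s) = sum_i w_mu,i(s_i) for each sequence; shape (N, M)."""
    codes = _as_codes(sequences, params.L)
    N = codes.shape[0]
    if params.M == 0:
        return np.zeros((N, 0))
    w_flat = params.w.reshape(params.M, -1)  # (M, L*4)
    out = np.empty((N, params.M))
    for start in range(0, N, block):
        chunk = codes[start:start + block]
        oh = seqdata.one_hot(chunk).reshape(len(chunk), -1)
        out[start:start + block] = oh @ w_flat.T
    return out


def fields_energy(params: RBMParams, codes: np.ndarray) -> np.ndarray:
    """sum_i g_i(s_i) per sequence."""
    return params.g[np.arange(params.L)[None, :], codes].sum(axis=1)


def unnormalized_log_likelihood(params: RBMParams, sequences) -> np.ndarray:
    """log ptilde(s) = fields + sum_mu Gamma_mu(I_mu(s)); shape (N,)."""
    codes = _as_codes(sequences, params.L)
    val = fields_energy(params, codes)
    if params.M:
        I = hidden_input(params, codes)
        val = val + log_partition(params.drelu, I).sum(axis=1)
    return val


def log_likelihood(params: RBMParams, sequences) -> np.ndarray:
    """Normalized log p(s); requires ``params.log_Z``."""
    if params.log_Z is None:
        raise ValueError("log_Z not set; run estimate_log_Z first")
    return unnormalized_log_likelihood(params, sequences) - params.log_Z


def mean_hidden_activity(params: RBMParams, sequences) -> np.ndarray:
    """<h_mu | s> for each sequence and unit; shape (N, M)."""
    I = hidden_input(params, sequences)
    return mean_activity(params.drelu, I)


# -- Gibbs sampling -------------------------------------------------------

def sample_h_given_s(params: RBMParams, codes: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    I = hidden_input(params, codes)
    return sample_hidden(params.drelu, I, rng)


def _sample_sites(logits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Categorical per (chain, site) from logits (N, L, 4), Gumbel-max."""
    gumbel = -np.log(-np.log(rng.random(logits.shape)))
    return np.argmax(logits + gumbel, axis=-1).astype(np.int8)


def sample_s_given_h(params: RBMParams, h: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    logits = params.g[None, :, :] + np.einsum("nm,mla->nla", h, params.w)
    return _sample_sites(logits, rng)


def _init_chains(params: RBMParams, n_chains: int, init,
                 rng: np.random.Generator) -> np.ndarray:
    if isinstance(init, np.ndarray):
        idx = rng.integers(0, len(init), size=n_chains)
        return init[idx].copy()
    if init == "random":
        return rng.integers(0, 4, size=(n_chains, params.L)).astype(np.int8)
    raise ValueError("init must be 'random' or an array of sequence codes")


def ags_sample(params: RBMParams, n_samples: int, n_sweeps: int = 100,
               n_chains: int = 100, init="random", seed: int = 0,
               return_codes: bool = False):
    """Draw sequences from p(s) by alternate Gibbs sampling.

    ``n_chains`` parallel chains are burnt in for ``n_sweeps`` full
    h->s sweeps; chain states are then collected once per sweep until
    ``n_samples`` sequences are gathered.
    """
    if n_samples <= 0 or n_sweeps <= 0 or n_chains <= 0:
        raise ValueError("sample counts must be positive")
    rng = np.random.default_rng(seed)
    s = _init_chains(params, n_chains, init, rng)
    for _ in range(n_sweeps):
        h = sample_h_given_s(params, s, rng)
        s = sample_s_given_h(params, h, rng)
    collected = [s.copy()]
    n_collected = n_chains
    while n_collected < n_samples:
        h = sample_h_given_s(params, s, rng)
        s = sample_s_given_h(params, h, rng)
        collected.append(s.copy())
        n_collected += n_chains
    codes = np.concatenate(collected, axis=0)[:n_samples]
    return codes if return_codes else seqdata.decode(codes)


def duplicated_sample(params: RBMParams, n_samples: int, n_sweeps: int = 100,
                      n_chains: int = 100, init="random", seed: int = 0,
                      return_codes: bool = False):
    """Draw sequences from p(s)^2 / sum p^2 via the duplication trick.

    The hidden layer is duplicated: two independent hidden vectors are
    sampled given s, and the visible update uses doubled fields plus the
    summed hidden contributions, which targets p(s)^2 exactly.
    """
    if n_samples <= 0 or n_sweeps <= 0 or n_chains <= 0:
        raise ValueError("sample counts must be positive")
    rng = np.random.default_rng(seed)
    s = _init_chains(params, n_chains, init, rng)

    def sweep(s):
        h1 = sample_h_given_s(params, s, rng)
        h2 = sample_h_given_s(params, s, rng)
        logits = 2.0 * params.g[None, :, :] + np.einsum(
            "nm,mla->nla", h1 + h2, params.w)
        return _sample_sites(logits, rng)

    for _ in range(n_sweeps):
        s = sweep(s)
    collected = [s.copy()]
    n_collected = n_chains
    while n_collected < n_samples:
        s = sweep(s)
        collected.append(s.copy())
        n_collected += n_chains
    codes = np.concatenate(collected, axis=0)[:n_samples]
    return codes if return_codes else seqdata.decode(codes)


# -- partition function ---------------------------------------------------

def fields_only_log_Z(params: RBMParams) -> float:
    """Exact log Z of the model with all weights set to zero."""
    val = logsumexp(params.g, axis=1).sum()
    if params.M:
        val += log_partition(params.drelu, np.zeros(params.M)).sum()
    return float(val)


def estimate_log_Z(params: RBMParams, n_steps: int = 1000, n_chains: int = 100,
                   seed: int = 0) -> tuple[float, float]:
    """Annealed-importance-sampling estimate of log Z.

    Interpolates from the fields-only model (weights scaled to zero,
    closed-form Z) to the full model by scaling the weights with
    beta in [0, 1]; one Gibbs sweep per temperature.  Returns the
    estimate and its standard error; exact (se = 0) when M = 0.
    """
    if n_steps <= 0 or n_chains <= 0:
        raise ValueError("n_steps and n_chains must be positive")
    log_Z0 = fields_only_log_Z(params)
    if params.M == 0:
        return log_Z0, 0.0

    rng = np.random.default_rng(seed)
    # init from the fields-only model
    logits = np.broadcast_to(params.g[None, :, :], (n_chains, params.L, 4))
    s = _sample_sites(np.array(logits), rng)
    betas = np.linspace(0.0, 1.0, n_steps + 1)
    log_w = np.zeros(n_chains)
    scaled = params.copy()
    I = hidden_input(params, s)
    gam_prev = log_partition(params.drelu, betas[0] * I).sum(axis=1)
    for beta in betas[1:]:
        gam_new = log_partition(params.drelu, beta * I).sum(axis=1)
        log_w += gam_new - gam_prev
        scaled.w = beta * params.w
        h = sample_h_given_s(scaled, s, rng)
        s = sample_s_given_h(scaled, h, rng)
        I = hidden_input(params, s)
        gam_prev = log_partition(params.drelu, beta * I).sum(axis=1)

    m = np.max(log_w)
    r = np.exp(log_w - m)
    mean_r = r.mean()
    se_log = r.std(ddof=1) / np.sqrt(n_chains) / mean_r
    return float(log_Z0 + m + np.log(mean_r)), float(se_log)


# -- exact enumeration (toy sizes) ----------------------------------------

def enumerate_codes(L: int) -> np.ndarray:
    """All 4^L sequences as an (4^L, L) integer array (guarded to L <= 12)."""
    if L > 12:
        raise ValueError("enumeration limited to L <= 12")
    grids = np.meshgrid(*([np.arange(4)] * L), indexing="ij")
    return np.stack([grid.ravel() for grid in grids], axis=1).astype(np.int8)


def exact_log_Z(params: RBMParams) -> float:
    """Brute-force log Z by enumerating sequences (analytic Gamma)."""
    codes = enumerate_codes(params.L)
    return float(logsumexp(unnormalized_log_likelihood(params, codes)))


# -- serialization --------------------------------------------------------

def save_params(params: RBMParams, path) -> None:
    """Write the model to a single HDF5 archive."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = _ARCHIVE_VERSION
        f.create_dataset("g", data=params.g)
        f.create_dataset("w", data=params.w)
        f.create_dataset("gamma_plus", data=params.drelu.gamma_plus)
        f.create_dataset("gamma_minus", data=params.drelu.gamma_minus)
        f.create_dataset("theta_plus", data=params.drelu.theta_plus)
        f.create_dataset("theta_minus", data=params.drelu.theta_minus)
        if params.log_Z is not None:
            f.attrs["log_Z"] = params.log_Z
            f.attrs["log_Z_se"] = params.log_Z_se
        f.attrs["metadata"] = json.dumps(params.metadata)


def load_params(path) -> RBMParams:
    with h5py.File(path, "r") as f:
        drelu = DReLUParams(
            f["gamma_plus"][...], f["gamma_minus"][...],
            f["theta_plus"][...], f["theta_minus"][...])
        params = RBMParams(
            f["g"][...], f["w"][...], drelu,
            log_Z=float(f.attrs["log_Z"]) if "log_Z" in f.attrs else None,
            log_Z_se=float(f.attrs["log_Z_se"]) if "log_Z_se" in f.attrs else None,
            metadata=json.loads(f.attrs.get("metadata", "{}")))
    return params
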