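"""Persistent contrastive divergence (PCD) training with L12 sparsity.

The objective is the (optionally count-weighted) mean data log-likelihood
minus an L12 weight penalty

    lambda * sum_mu ( sum_i sum_a |w_mu,i(a)| )^2,

which drives whole rows of each hidden unit's weight vector to zero and
makes the learned motifs readable.  Two weighting modes are supported:
``counts`` weights every sequence by its read count (the model then
concentrates on the few highest-count binders) and ``unique`` treats each
distinct sequence once (better generalization and more diverse
generation).  Gradients use exact conditional hidden moments in the
positive phase; the negative phase uses persistent Gibbs chains that are
advanced a few sweeps per update and never reset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rbm, seqdata
from .drelu import DReLUParams, signed_moments

_GAMMA_FLOOR = 0.05


@dataclass
class TrainConfig:
    """Hyperparameters for :func:`pcd_train`.

    Defaults follow the reference setup for these data: ``M = 70`` hidden
    units for 20-nt single loops (use 90 for 40-nt double loops),
    ``lambda_l12 = 1e-3``.  Optimizer constants (batch 100, learning rate
    5e-3 with linear decay, 100 persistent chains, 10 Gibbs steps per
    update) are this package's choices, validated on enumerable models.
    """

    mode: str = "unique"  # 'counts' or 'unique'
    M: int = 70
    lambda_l12: float = 1e-3
    learning_rate: float = 5e-3
    lr_decay: float = 0.95  # fraction of the learning rate annealed away
    batch_size: int = 100
    n_persistent_chains: int = 100
    n_gibbs_steps: int = 10
    epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("counts", "unique"):
            raise ValueError("mode must be 'counts' or 'unique'")
        for name in ("M", "batch_size", "n_persistent_chains",
                     "n_gibbs_steps", "epochs"):
            if getattr(self, name) < (0 if name == "M" else 1):
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0 or self.lambda_l12 < 0:
            raise ValueError("invalid learning_rate or lambda_l12")


@dataclass
class TrainingTrace:
    records: list = field(default_factory=list)

    def append(self, **kwargs):
        self.records.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def l12_penalty(w: np.ndarray) -> tuple[float, np.ndarray]:
    """L12 penalty and its (sub)gradient, without the lambda factor.

    value = sum_mu ( sum_i,a |w_mu,i(a)| )^2 ; the subgradient at exact
    zeros is 0.
    """
    w = np.asarray(w, dtype=np.float64)
    row_l1 = np.abs(w).reshape(w.shape[0], -1).sum(axis=1) if w.size else \
        np.zeros(w.shape[0])
    value = float(np.sum(row_l1**2))
    grad = 2.0 * row_l1[:, None, None] * np.sign(w)
    return value, grad


def _moment_stats(params: rbm.RBMParams, codes: np.ndarray,
                  weights: np.ndarray | None):
    """Weighted data moments needed for the gradient.

    Returns (g_stat (L,4), w_stat (M,L,4), hp, hm, hp2, hm2 each (M,)).
    """
    B = len(codes)
    if weights is None:
        weights = np.ones(B)
    wn = weights / weights.mean()
    oh = seqdata.one_hot(codes)  # (B, L, 4)
    g_stat = np.einsum("b,bla->la", wn, oh) / B
    if params.M == 0:
        z = np.zeros(0)
        return g_stat, np.zeros_like(params.w), z, z, z, z
    I = rbm.hidden_input(params, codes)
    hp, hm, hp2, hm2 = signed_moments(params.drelu, I)
    mean_h = hp + hm
    w_stat = np.einsum("b,bm,bla->mla", wn, mean_h, oh) / B
    stat = lambda x: np.einsum("b,bm->m", wn, x) / B
    return g_stat, w_stat, stat(hp), stat(hm), stat(hp2), stat(hm2)


def initialize_params(table: seqdata.RoundTable, M: int, mode: str,
                      seed: int, w_scale: float = 0.01) -> rbm.RBMParams:
    """Fields from (weighted) empirical site frequencies; small random w;
    dReLU units start as unit Gaussians (gamma = 1, theta = 0)."""
    rng = np.random.default_rng(seed)
    weights = table.counts.astype(float) if mode == "counts" else \
        np.ones(table.n_unique)
    oh = seqdata.one_hot(table.codes)
    freq = np.einsum("b,bla->la", weights, oh) / weights.sum()
    g = np.log(freq + 1e-6)
    g -= g.mean(axis=1, keepdims=True)
    w = rng.normal(0.0, w_scale, size=(M, table.L, 4))
    drelu = DReLUParams(np.ones(M), np.ones(M), np.zeros(M), np.zeros(M))
    return rbm.RBMParams(g, w, drelu)


def pcd_train(table: seqdata.RoundTable,
              config: TrainConfig) -> tuple[rbm.RBMParams, TrainingTrace]:
    """Fit an RBM to a round table by persistent contrastive divergence.

    Deterministic given ``config.seed``.  Raises ``RuntimeError`` (with
    the partial trace attached as ``.trace``) if parameters diverge.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    params = initialize_params(table, cfg.M, cfg.mode, cfg.seed)
    N = table.n_unique
    if N < 1:
        raise ValueError("empty training table")
    counts = table.counts.astype(float)
    codes_all = table.codes

    # persistent chains start from data sequences
    chain_idx = rng.integers(0, N, size=cfg.n_persistent_chains)
    chains = codes_all[chain_idx].copy()

    n_batches = max(1, N // cfg.batch_size)
    total_updates = cfg.epochs * n_batches
    trace = TrainingTrace()
    t = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(N)
        grad_norm = 0.0
        for b in range(n_batches):
            idx = perm[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            if idx.size == 0:
                continue
            batch = codes_all[idx]
            w_batch = counts[idx] if cfg.mode == "counts" else None

            pos = _moment_stats(params, batch, w_batch)
            for _ in range(cfg.n_gibbs_steps):
                h = rbm.sample_h_given_s(params, chains, rng)
                chains = rbm.sample_s_given_h(params, h, rng)
            neg = _moment_stats(params, chains, None)

            lr = cfg.learning_rate * (1.0 - cfg.lr_decay * t / max(1, total_updates))
            _, pen_grad = l12_penalty(params.w)
            dg = pos[0] - neg[0]
            dw = pos[1] - neg[1] - cfg.lambda_l12 * pen_grad
            params.g += lr * dg
            params.w += lr * dw
            if params.M:
                d = params.drelu
                # dGamma/dtheta = -<h_+/->, dGamma/dgamma = -<h^2_+/->/2,
                # so the ascent direction flips the (data - model) moments
                new_tp = d.theta_plus - lr * (pos[2] - neg[2])
                new_tm = d.theta_minus - lr * (pos[3] - neg[3])
                new_gp = d.gamma_plus - 0.5 * lr * (pos[4] - neg[4])
                new_gm = d.gamma_minus - 0.5 * lr * (pos[5] - neg[5])
                params.drelu = DReLUParams(
                    np.maximum(new_gp, _GAMMA_FLOOR),
                    np.maximum(new_gm, _GAMMA_FLOOR),
                    new_tp, new_tm)
            grad_norm = float(np.sqrt((dg**2).sum() + (dw**2).sum()))
            t += 1

        finite = (np.isfinite(params.g).all() and np.isfinite(params.w).all()
                  and np.isfinite(params.drelu.theta_plus).all())
        mean_ull = float(np.average(
            rbm.unnormalized_log_likelihood(params, codes_all),
            weights=counts if cfg.mode == "counts" else None))
        sparsity = float(np.mean(np.abs(params.w) < 1e-3)) if params.w.size else 1.0
        trace.append(epoch=epoch, mean_train_ull=mean_ull,
                     grad_norm=grad_norm, weight_sparsity=sparsity)
        if not finite:
            err = RuntimeError(f"training diverged at epoch {epoch}")
            err.trace = trace
            raise err

    params.metadata = {
        "mode": cfg.mode, "M": cfg.M, "lambda_l12": cfg.lambda_l12,
        "epochs": cfg.epochs, "seed": cfg.seed,
        "n_train_unique": int(N), "L": int(table.L),
    }
    return params, trace


def evaluate_heldout(params: rbm.RBMParams, validation: seqdata.RoundTable,
                     weighting: str = "unique", seed: int = 0) -> float:
    """Weighted mean normalized log-likelihood of a held-out table.

    Estimates log Z by annealed importance sampling if not yet set on
    ``params`` (cached on the params object afterwards).
    """
    if validation.n_unique == 0:
        raise ValueError("empty validation table")
    if weighting not in ("counts", "unique"):
        raise ValueError("weighting must be 'counts' or 'unique'")
    if params.log_Z is None:
        params.log_Z, params.log_Z_se = rbm.estimate_log_Z(params, seed=seed)
    ll = rbm.log_likelihood(params, validation.codes)
    weights = validation.counts if weighting == "counts" else None
    return float(np.average(ll, weights=weights))
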