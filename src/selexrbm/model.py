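"""Model/Results objects: the user-facing fitting interface.

Follows the familiar two-object pattern: :class:`AptamerRBM` holds the
data and hyperparameters, its :meth:`~AptamerRBM.fit` runs persistent
contrastive divergence and returns an :class:`RBMResults` carrying the
trained parameters, the training trace, and scoring / sampling /
introspection methods.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from . import interpret, rbm, seqdata, training


class AptamerRBM:
    """dReLU Restricted Boltzmann Machine over fixed-length DNA sequences.

    Parameters
    ----------
    data : RoundTable
        Training sequences with counts.
    n_hidden : int
        Number of hidden units M (70 is a good default for 20-nt loops,
        90 for 40-nt double loops).
    mode : {'unique', 'counts'}
        Whether each distinct sequence counts once or by its read count.
    lambda_l12 : float
        L12 sparsity strength on the weights.

    Further optimizer options are forwarded to
    :class:`selexrbm.training.TrainConfig`.
    """

    def __init__(self, data: seqdata.RoundTable, n_hidden: int = 70,
                 mode: str = "unique", lambda_l12: float = 1e-3, **config):
        self.data = data
        self.config = training.TrainConfig(
            mode=mode, M=n_hidden, lambda_l12=lambda_l12, **config)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, round_index=None, **kwargs):
        """Build from a DataFrame with 'sequence' and optional 'count'."""
        counts = frame["count"].to_numpy() if "count" in frame else \
            np.ones(len(frame), dtype=np.int64)
        table = seqdata.RoundTable.from_records(
            zip(frame["sequence"], counts), round_index=round_index)
        return cls(table, **kwargs)

    def fit(self, epochs: int | None = None, seed: int | None = None,
            **overrides) -> "RBMResults":
        cfg = self.config
        if epochs is not None:
            overrides["epochs"] = epochs
        if seed is not None:
            overrides["seed"] = seed
        if overrides:
            cfg = training.TrainConfig(**{**cfg.__dict__, **overrides})
        params, trace = training.pcd_train(self.data, cfg)
        return RBMResults(self, params, trace)


class RBMResults:
    """Fitted RBM: scores, samples, introspection, persistence."""

    def __init__(self, model: AptamerRBM | None, params: rbm.RBMParams,
                 trace: training.TrainingTrace | None = None):
        self.model = model
        self.params = params
        self.trace = trace

    # -- scoring ----------------------------------------------------------
    def log_likelihood(self, sequences, normalized: bool = False) -> np.ndarray:
        """Sequence scores log ptilde(s) (or log p(s) when normalized)."""
        if normalized:
            if self.params.log_Z is None:
                self.estimate_log_Z()
            return rbm.log_likelihood(self.params, sequences)
        return rbm.unnormalized_log_likelihood(self.params, sequences)

    def estimate_log_Z(self, n_steps: int = 1000, n_chains: int = 100,
                       seed: int = 0) -> tuple[float, float]:
        lz, se = rbm.estimate_log_Z(self.params, n_steps, n_chains, seed)
        self.params.log_Z, self.params.log_Z_se = lz, se
        return lz, se

    # -- generation -------------------------------------------------------
    def sample(self, n: int, n_sweeps: int = 100, n_chains: int = 100,
               seed: int = 0, squared: bool = False, **kwargs):
        """Generate sequences from p(s), or from p(s)^2 (``squared``)."""
        fn = rbm.duplicated_sample if squared else rbm.ags_sample
        return fn(self.params, n, n_sweeps=n_sweeps, n_chains=n_chains,
                  seed=seed, **kwargs)

    # -- introspection ----------------------------------------------------
    def hidden_inputs(self, sequences) -> np.ndarray:
        return rbm.hidden_input(self.params, sequences)

    def weight_norms(self) -> pd.DataFrame:
        return interpret.frobenius_norms(self.params)

    def summary(self) -> str:
        p = self.params
        buf = io.StringIO()
        meta = p.metadata
        buf.write("Aptamer dReLU RBM results\n")
        buf.write("=" * 44 + "\n")
        buf.write(f"Visible sites (L):        {p.L}\n")
        buf.write(f"Hidden units (M):         {p.M}\n")
        buf.write(f"Training mode:            {meta.get('mode', '?')}\n")
        buf.write(f"L12 strength:             {meta.get('lambda_l12', '?')}\n")
        buf.write(f"Epochs / seed:            {meta.get('epochs', '?')}"
                  f" / {meta.get('seed', '?')}\n")
        buf.write(f"Unique training seqs:     {meta.get('n_train_unique', '?')}\n")
        sparsity = float(np.mean(np.abs(p.w) < 1e-3)) if p.w.size else 1.0
        buf.write(f"Weight sparsity (<1e-3):  {sparsity:.3f}\n")
        if p.log_Z is not None:
            buf.write(f"log Z (AIS):              {p.log_Z:.3f}"
                      f" +- {p.log_Z_se:.3f}\n")
        if self.trace is not None and self.trace.records:
            last = self.trace.records[-1]
            buf.write(f"Final mean train score:   {last['mean_train_ull']:.3f}\n")
        norms = interpret.frobenius_norms(p)
        if len(norms):
            top = ", ".join(f"{r.unit}:{r.frobenius_norm:.2f}"
                            for r in norms.head(3).itertuples())
            buf.write(f"Top weight norms:         {top}\n")
        return buf.getvalue()

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        rbm.save_params(self.params, path)

    @classmethod
    def load(cls, path) -> "RBMResults":
        return cls(None, rbm.load_params(path))
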