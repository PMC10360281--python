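"""Contrastive channel: fragment-attentive view vs atom-level view, InfoNCE.

The fragment view of a molecule pools node embeddings into fragment means,
projects them to queries/keys/values, scores each fragment with a scaled
dot-product logit, softmaxes over the molecule's own fragments and sums the
weighted values.  The atom view is the plain readout of node embeddings.
InfoNCE aligns the two views of the same molecule against all atom views in
the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "AttentionParams",
    "ContrastiveBatch",
    "init_attention_params",
    "fragment_mean_pool",
    "attentive_pool",
    "infonce_loss",
]


@dataclass
class AttentionParams:
    """Query/key/value projections of the fragment attention network."""

    w_q: Tensor
    w_k: Tensor
    w_v: Tensor

    def __post_init__(self):
        d = self.w_q.shape
        if len(d) != 2 or d[0] != d[1]:
            raise ValueError("attention projections must be square D x D")
        if self.w_k.shape != d or self.w_v.shape != d:
            raise ValueError("attention projections must share one shape")


@dataclass
class ContrastiveBatch:
    """The two pooled views for one optimization step."""

    fragment_view: Tensor   # (B, D) attentive fragment pooling
    atom_view: Tensor       # (B, D) plain readout
    temperature: float

    def __post_init__(self):
        if self.fragment_view.shape != self.atom_view.shape:
            raise ValueError("view matrices must have equal shapes")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def init_attention_params(hidden_dim: int, rng: np.random.Generator) -> dict[str, Tensor]:
    return {
        "attn.w_q": ad.parameter(ad.glorot(rng, (hidden_dim, hidden_dim))),
        "attn.w_k": ad.parameter(ad.glorot(rng, (hidden_dim, hidden_dim))),
        "attn.w_v": ad.parameter(ad.glorot(rng, (hidden_dim, hidden_dim))),
    }


def fragment_mean_pool(node_embeddings, frag_of_atom, num_fragments: int) -> Tensor:
    """h_f^m: arithmetic mean of node embeddings within each fragment."""
    return ad.segment_mean(node_embeddings, frag_of_atom, num_fragments)


def attentive_pool(
    fragment_embeddings,
    frag_mol: np.ndarray,
    num_mols: int,
    params: AttentionParams,
    logit_mode: str = "per_fragment",
) -> Tensor:
    """Fragment-attention pooling into one vector per molecule.

    Each fragment's logit is its scaled query-key dot product q.k/sqrt(D);
    weights are softmaxed over the molecule's own fragments and applied to
    the projected values.  ``logit_mode="batch_mean"`` keeps the literal
    batch-averaged single logit (which makes the weights uniform within each
    molecule) for comparison.
    """
    if logit_mode not in ("per_fragment", "batch_mean"):
        raise ValueError(f"unknown logit_mode {logit_mode!r}")
    f = ad.constant(fragment_embeddings)
    d = f.shape[1]
    q = ad.matmul(f, params.w_q)
    k = ad.matmul(f, params.w_k)
    v = ad.matmul(f, params.w_v)
    logits = ad.mul(ad.tsum(ad.mul(q, k), axis=1), 1.0 / np.sqrt(d))
    if logit_mode == "batch_mean":
        shared = ad.tmean(logits)
        logits = ad.add(ad.mul(logits, 0.0), shared)
    alpha = ad.segment_softmax(logits, frag_mol, num_mols)
    weighted = ad.mul(v, ad.reshape(alpha, (-1, 1)))
    return ad.segment_sum(weighted, frag_mol, num_mols)


def attention_weights(
    fragment_embeddings,
    frag_mol: np.ndarray,
    num_mols: int,
    params: AttentionParams,
    logit_mode: str = "per_fragment",
) -> np.ndarray:
    """The per-fragment softmax weights (a probability vector per molecule)."""
    f = ad.constant(fragment_embeddings)
    d = f.shape[1]
    q = ad.matmul(f, params.w_q)
    k = ad.matmul(f, params.w_k)
    logits = ad.mul(ad.tsum(ad.mul(q, k), axis=1), 1.0 / np.sqrt(d))
    if logit_mode == "batch_mean":
        logits = ad.add(ad.mul(logits, 0.0), ad.tmean(logits))
    return ad.segment_softmax(logits, frag_mol, num_mols).data


def infonce_loss(batch: ContrastiveBatch) -> Tensor:
    """InfoNCE with cosine-similarity critic.

    L_C = (1/|B|) sum_i -log exp(cos(a_i, p_i)/tau) / sum_j exp(cos(a_i, p_j)/tau)

    Anchors are fragment views, positives the same molecule's atom view,
    negatives all other atom views in the batch (the denominator includes
    j = i).  Requires batch size >= 2, otherwise there is no negative and the
    task is degenerate.
    """
    b = batch.fragment_view.shape[0]
    if b < 2:
        raise ValueError("InfoNCE needs batch size >= 2")
    sims = ad.cosine_matrix(batch.fragment_view, batch.atom_view)
    logits = ad.mul(sims, 1.0 / batch.temperature)
    lse = ad.logsumexp_rows(logits)
    idx = np.arange(b)
    pos = ad.take2d(logits, idx, idx)
    return ad.tmean(ad.add(lse, ad.mul(pos, -1.0)))
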