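"""Generative channel: fragment-level masked autoencoding.

A random subset of atoms has its features replaced by a [MASK] token; the
shared encoder runs with message passing restricted to intra-fragment bonds,
the masked positions' hidden states are re-masked with a learned decoder
token, and a single GIN decoder layer (also fragment-restricted) plus a
linear head reconstruct the clean atom-feature embeddings.  Reconstructions
are scored with the scaled cosine error (1 - cos)^gamma averaged per
molecule and then over the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoder import EncoderConfig, GraphBatch, _init_gin_layer, encode, gin_layer
from .mol_io import ATOM_MASK_INDEX, MolecularGraph

__all__ = [
    "MaskSpec",
    "GenerativeConfig",
    "init_decoder_params",
    "sample_mask",
    "reconstruct_batch",
    "scaled_cosine_error",
    "generative_loss",
]


@dataclass
class MaskSpec:
    """The masked atom subset of one molecule."""

    masked_atoms: np.ndarray      # sorted atom indices within the molecule
    mask_ratio: float
    mask_token: int = ATOM_MASK_INDEX


@dataclass
class GenerativeConfig:
    mask_ratio: float = 0.3       # fraction of atoms masked per molecule
    gamma: float = 2.0            # scaled-cosine-error exponent, >= 1
    decoder_layers: int = 1
    remask_before_decode: bool = True

    def __post_init__(self):
        if not 0.0 < self.mask_ratio < 1.0:
            raise ValueError("mask_ratio must be in (0, 1)")
        if self.gamma < 1.0:
            raise ValueError("gamma must be >= 1")
        if self.decoder_layers < 1:
            raise ValueError("decoder_layers must be >= 1")


def init_decoder_params(
    config: EncoderConfig,
    gen_config: GenerativeConfig,
    rng: np.random.Generator,
) -> dict[str, Tensor]:
    d = config.hidden_dim
    p: dict[str, Tensor] = {
        "dec.mask_token": ad.parameter(ad.glorot(rng, (1, d))),
    }
    for k in range(gen_config.decoder_layers):
        p.update(_init_gin_layer(f"dec.{k}", d, rng))
    p["dec.out_w"] = ad.parameter(ad.glorot(rng, (d, d)))
    p["dec.out_b"] = ad.parameter(np.zeros(d))
    return p


def sample_mask(
    graph: MolecularGraph, ratio: float, rng: np.random.Generator
) -> MaskSpec:
    """Uniformly sample floor(ratio * n) atoms, at least 1 when n >= 2.

    Single-atom molecules get an empty mask and contribute zero generative
    loss.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("mask ratio must be in (0, 1)")
    n = graph.num_atoms
    count = int(np.floor(ratio * n))
    if count == 0 and n >= 2:
        count = 1
    chosen = np.sort(rng.choice(n, size=count, replace=False)) if count else np.zeros(0, dtype=np.int64)
    return MaskSpec(masked_atoms=chosen.astype(np.int64), mask_ratio=ratio)


def reconstruct_batch(
    batch: GraphBatch,
    masks: list[MaskSpec],
    params: dict[str, Tensor],
    enc_config: EncoderConfig,
    gen_config: GenerativeConfig,
    train: bool = False,
) -> tuple[Tensor, Tensor, np.ndarray]:
    """Reconstruct masked atoms' clean feature embeddings.

    Returns ``(reconstructions (M, D), targets (M, D) detached, mol_of_masked
    (M,))`` where M is the total number of masked atoms in the batch.  The
    batch must carry fragment assignments (``intra_bond_mask``).  In eval
    mode (the default) batch normalization uses stored running statistics,
    so a masked atom's reconstruction depends only on its own fragment; in
    train mode batch statistics introduce weak cross-fragment coupling.
    """
    if batch.intra_bond_mask is None:
        raise ValueError("batch must be built with fragment assignments")
    if len(masks) != batch.num_mols:
        raise ValueError("one MaskSpec per molecule required")
    masked_global = np.concatenate(
        [m.masked_atoms + batch.node_offsets[i] for i, m in enumerate(masks)]
    ).astype(np.int64) if masks else np.zeros(0, dtype=np.int64)
    mol_of_masked = batch.mol_of_atom[masked_global]

    # clean targets: embedded atom features, detached so the loss cannot be
    # gamed by collapsing the embedding tables
    target = (
        ad.gather_rows(params["atom_emb_type"], batch.atom_type[masked_global])
        + ad.gather_rows(params["atom_emb_chir"], batch.atom_chir[masked_global])
    ).detach()

    # corrupt features at masked positions
    types = batch.atom_type.copy()
    chirs = batch.atom_chir.copy()
    types[masked_global] = ATOM_MASK_INDEX
    chirs[masked_global] = 0

    h, _ = encode(
        batch,
        params,
        enc_config,
        edge_mask=batch.intra_bond_mask,
        atom_features_override=(types, chirs),
        train=train,
    )
    if gen_config.remask_before_decode and len(masked_global):
        ind = np.zeros((batch.num_atoms, 1))
        ind[masked_global] = 1.0
        h = ad.add(ad.mul(h, 1.0 - ind), ad.mul(params["dec.mask_token"], ind))
    for k in range(gen_config.decoder_layers):
        h = gin_layer(
            h, batch, params, f"dec.{k}",
            edge_mask=batch.intra_bond_mask,
            final_relu=(k < gen_config.decoder_layers - 1),
            norm=enc_config.norm,
            train=train,
        )
    z = ad.linear(h, params["dec.out_w"], params["dec.out_b"])
    recon = ad.gather_rows(z, masked_global)
    return recon, target, mol_of_masked


def scaled_cosine_error(
    targets,
    reconstructions,
    mol_of_masked: np.ndarray,
    num_mols: int,
    gamma: float,
) -> Tensor:
    """L_G = (1/|B|) sum_i (1/|V_i|) sum_{v in V_i} (1 - cos(x_v, z_v))^gamma.

    Molecules with no masked atom contribute zero but still count in |B|.
    Raises on zero-norm target rows (the cosine is undefined there).
    """
    t = ad.constant(targets)
    z = ad.constant(reconstructions)
    if len(mol_of_masked) == 0:
        return ad.constant(0.0)
    t_norms = np.linalg.norm(t.data, axis=1)
    if (t_norms == 0).any():
        raise FloatingPointError("zero-norm target vector in scaled cosine error")
    dots = ad.tsum(ad.mul(t, z), axis=1)
    norm_prod = ad.reshape(ad.mul(ad.row_norms(t), ad.row_norms(z)), (-1,))
    cos = ad.mul(dots, ad.power(norm_prod, -1.0))
    per_node = ad.power(ad.add(1.0, ad.mul(cos, -1.0)), gamma)
    per_mol = ad.segment_mean(per_node, mol_of_masked, num_mols)
    return ad.tmean(per_mol)


def generative_loss(
    batch: GraphBatch,
    masks: list[MaskSpec],
    params: dict[str, Tensor],
    enc_config: EncoderConfig,
    gen_config: GenerativeConfig,
    train: bool = False,
) -> Tensor:
    """Full generative channel: reconstruct then score."""
    recon, target, mol_of_masked = reconstruct_batch(
        batch, masks, params, enc_config, gen_config, train=train
    )
    return scaled_cosine_error(
        target, recon, mol_of_masked, batch.num_mols, gen_config.gamma
    )
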