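"""GIN message-passing encoder.

Node features are embedded by summing per-field embedding tables; each layer
aggregates neighbor messages (neighbor embedding plus embedded edge feature,
summed over neighbors, with a self-loop edge carrying a dedicated bond-type
slot), passes the aggregate through a two-layer perceptron and normalizes
per node.  The molecule embedding is the mean (or sum) of final-layer node
embeddings.

Message passing can be restricted to a subset of bonds (``edge_mask``); the
generative channel uses this to keep information inside BRICS fragments.
With all bonds enabled the restricted call is bit-for-bit identical to the
unrestricted one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fragmentation import FragmentAssignment
from .mol_io import (
    BOND_SELF_LOOP_INDEX,
    NUM_ATOM_TYPE_SLOTS,
    NUM_BOND_DIRECTIONS,
    NUM_BOND_TYPE_SLOTS,
    NUM_CHIRALITY_TAGS,
    MolecularGraph,
)

__all__ = ["EncoderConfig", "EmbeddingSet", "GraphBatch", "init_encoder_params", "encode"]


@dataclass
class EncoderConfig:
    num_layers: int = 5
    hidden_dim: int = 300
    dropout: float = 0.0          # 0 during pretraining, 0.5 downstream
    readout: str = "mean"         # "mean" | "sum"
    norm: str = "batch"           # "batch" (running-stat BN) | "layer" (per-node)

    def __post_init__(self):
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.readout not in ("mean", "sum"):
            raise ValueError("readout must be 'mean' or 'sum'")
        if self.norm not in ("batch", "layer"):
            raise ValueError("norm must be 'batch' or 'layer'")


@dataclass
class EmbeddingSet:
    """Per-node and pooled embeddings for one molecule."""

    node_embeddings: np.ndarray    # (num_atoms, D)
    molecule_embedding: np.ndarray  # (D,)


@dataclass
class GraphBatch:
    """A disjoint union of molecular graphs with flat index arrays."""

    atom_type: np.ndarray          # (N,)
    atom_chir: np.ndarray          # (N,)
    mol_of_atom: np.ndarray        # (N,)
    num_mols: int
    bond_src: np.ndarray           # (E,) undirected bonds, stored once
    bond_dst: np.ndarray           # (E,)
    bond_type: np.ndarray          # (E,)
    bond_dir: np.ndarray           # (E,)
    node_offsets: np.ndarray       # (num_mols + 1,)
    frag_of_atom: np.ndarray | None = None   # (N,) globally offset fragment ids
    num_frags: int = 0
    frag_mol: np.ndarray | None = None       # (num_frags,) molecule of each fragment
    intra_bond_mask: np.ndarray | None = None  # (E,) True where bond stays in fragment

    @property
    def num_atoms(self) -> int:
        return len(self.atom_type)

    @property
    def num_bonds(self) -> int:
        return len(self.bond_src)

    @classmethod
    def from_graphs(
        cls,
        graphs: list[MolecularGraph],
        assignments: list[FragmentAssignment] | None = None,
    ) -> "GraphBatch":
        types, chirs, mol_ids = [], [], []
        src, dst, bt, bd = [], [], [], []
        frag_ids: list[np.ndarray] = []
        frag_mol: list[int] = []
        offsets = [0]
        frag_offset = 0
        for i, g in enumerate(graphs):
            off = offsets[-1]
            types.append(g.atom_features[:, 0])
            chirs.append(g.atom_features[:, 1])
            mol_ids.append(np.full(g.num_atoms, i))
            if g.num_bonds:
                src.append(g.bond_list[:, 0] + off)
                dst.append(g.bond_list[:, 1] + off)
                bt.append(g.bond_features[:, 0])
                bd.append(g.bond_features[:, 1])
            if assignments is not None:
                fa = assignments[i]
                frag_ids.append(fa.fragment_of_atom + frag_offset)
                frag_mol.extend([i] * fa.num_fragments)
                frag_offset += fa.num_fragments
            offsets.append(off + g.num_atoms)

        def cat(parts, dtype=np.int64):
            return (np.concatenate(parts).astype(dtype) if parts
                    else np.zeros(0, dtype=dtype))

        batch = cls(
            atom_type=cat(types),
            atom_chir=cat(chirs),
            mol_of_atom=cat(mol_ids),
            num_mols=len(graphs),
            bond_src=cat(src),
            bond_dst=cat(dst),
            bond_type=cat(bt),
            bond_dir=cat(bd),
            node_offsets=np.asarray(offsets, dtype=np.int64),
        )
        if assignments is not None:
            batch.frag_of_atom = cat(frag_ids)
            batch.num_frags = frag_offset
            batch.frag_mol = np.asarray(frag_mol, dtype=np.int64)
            if batch.num_bonds:
                batch.intra_bond_mask = (
                    batch.frag_of_atom[batch.bond_src]
                    == batch.frag_of_atom[batch.bond_dst]
                )
            else:
                batch.intra_bond_mask = np.zeros(0, dtype=bool)
        return batch


def init_encoder_params(
    config: EncoderConfig, rng: np.random.Generator
) -> dict[str, Tensor]:
    """Glorot-initialized encoder parameters, keyed by dotted names."""
    d = config.hidden_dim
    p: dict[str, Tensor] = {
        "atom_emb_type": ad.parameter(ad.glorot(rng, (NUM_ATOM_TYPE_SLOTS, d))),
        "atom_emb_chir": ad.parameter(ad.glorot(rng, (NUM_CHIRALITY_TAGS, d))),
    }
    for k in range(config.num_layers):
        p.update(_init_gin_layer(f"enc.{k}", d, rng))
    return p


def _init_gin_layer(prefix: str, d: int, rng: np.random.Generator) -> dict[str, Tensor]:
    return {
        f"{prefix}.edge_emb_type": ad.parameter(ad.glorot(rng, (NUM_BOND_TYPE_SLOTS, d))),
        f"{prefix}.edge_emb_dir": ad.parameter(ad.glorot(rng, (NUM_BOND_DIRECTIONS, d))),
        f"{prefix}.w1": ad.parameter(ad.glorot(rng, (d, 2 * d))),
        f"{prefix}.b1": ad.parameter(np.zeros(2 * d)),
        f"{prefix}.w2": ad.parameter(ad.glorot(rng, (2 * d, d))),
        f"{prefix}.b2": ad.parameter(np.zeros(d)),
        f"{prefix}.norm_g": ad.parameter(np.ones(d)),
        f"{prefix}.norm_b": ad.parameter(np.zeros(d)),
        # batch-norm running buffers (non-trainable; read as constants)
        f"{prefix}.norm_m": Tensor(np.zeros(d)),
        f"{prefix}.norm_v": Tensor(np.ones(d)),
    }


def gin_layer(
    h: Tensor,
    batch: GraphBatch,
    params: dict[str, Tensor],
    prefix: str,
    edge_mask: np.ndarray | None = None,
    final_relu: bool = True,
    norm: str = "batch",
    train: bool = False,
) -> Tensor:
    """One GIN layer: sum-aggregate neighbor + edge messages, MLP, layer norm."""
    n = batch.num_atoms
    if edge_mask is None:
        src, dst = batch.bond_src, batch.bond_dst
        bt, bd = batch.bond_type, batch.bond_dir
    else:
        keep = np.asarray(edge_mask, dtype=bool)
        src, dst = batch.bond_src[keep], batch.bond_dst[keep]
        bt, bd = batch.bond_type[keep], batch.bond_dir[keep]
    # expand stored undirected bonds to both directions
    e_src = np.concatenate([src, dst])
    e_dst = np.concatenate([dst, src])
    e_bt = np.concatenate([bt, bt])
    e_bd = np.concatenate([bd, bd])

    emb_t = params[f"{prefix}.edge_emb_type"]
    emb_d = params[f"{prefix}.edge_emb_dir"]
    if len(e_src):
        msg = (
            ad.gather_rows(h, e_src)
            + ad.gather_rows(emb_t, e_bt)
            + ad.gather_rows(emb_d, e_bd)
        )
        agg = ad.segment_sum(msg, e_dst, n)
    else:
        agg = ad.constant(np.zeros_like(h.data))
    # self-loop message with its dedicated bond-type slot
    self_msg = (
        h
        + ad.gather_rows(emb_t, np.array([BOND_SELF_LOOP_INDEX]))
        + ad.gather_rows(emb_d, np.array([0]))
    )
    agg = agg + self_msg

    z = ad.relu(ad.linear(agg, params[f"{prefix}.w1"], params[f"{prefix}.b1"]))
    z = ad.linear(z, params[f"{prefix}.w2"], params[f"{prefix}.b2"])
    if norm == "batch":
        z = ad.batch_norm(
            z, params[f"{prefix}.norm_g"], params[f"{prefix}.norm_b"],
            params[f"{prefix}.norm_m"], params[f"{prefix}.norm_v"], train=train,
        )
    else:
        z = ad.layer_norm(z, params[f"{prefix}.norm_g"], params[f"{prefix}.norm_b"])
    if final_relu:
        z = ad.relu(z)
    return z


def encode(
    batch: GraphBatch,
    params: dict[str, Tensor],
    config: EncoderConfig,
    edge_mask: np.ndarray | None = None,
    atom_features_override: tuple[np.ndarray, np.ndarray] | None = None,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor]:
    """Run the encoder over a batch.

    Returns ``(node_embeddings (N, D), molecule_embeddings (B, D))``.
    ``edge_mask`` restricts message passing to a bond subset (self-loops are
    always kept); ``atom_features_override`` substitutes corrupted features
    for masked-autoencoding without touching the graph object.
    """
    _check_params(params, config)
    if config.dropout > 0.0 and train and rng is None:
        raise ValueError("dropout requires an rng in train mode")
    types = batch.atom_type if atom_features_override is None else atom_features_override[0]
    chirs = batch.atom_chir if atom_features_override is None else atom_features_override[1]
    h = ad.gather_rows(params["atom_emb_type"], types) + ad.gather_rows(
        params["atom_emb_chir"], chirs
    )
    for k in range(config.num_layers):
        h = gin_layer(
            h, batch, params, f"enc.{k}",
            edge_mask=edge_mask,
            final_relu=(k < config.num_layers - 1),
            norm=config.norm,
            train=train,
        )
        if train and config.dropout > 0.0:
            h = ad.dropout(h, config.dropout, rng, train=True)
    if config.readout == "mean":
        hg = ad.segment_mean(h, batch.mol_of_atom, batch.num_mols)
    else:
        hg = ad.segment_sum(h, batch.mol_of_atom, batch.num_mols)
    return h, hg


def encode_molecule(
    graph: MolecularGraph,
    params: dict[str, Tensor],
    config: EncoderConfig,
) -> EmbeddingSet:
    """Convenience eval-mode wrapper for a single molecule."""
    batch = GraphBatch.from_graphs([graph])
    h, hg = encode(batch, params, config)
    return EmbeddingSet(node_embeddings=h.data.copy(), molecule_embedding=hg.data[0].copy())


def _check_params(params: dict[str, Tensor], config: EncoderConfig) -> None:
    d = config.hidden_dim
    if params["atom_emb_type"].shape[1] != d:
        raise ValueError("parameter width does not match config.hidden_dim")
    last = f"enc.{config.num_layers - 1}.w1"
    if last not in params:
        raise ValueError("parameter set does not match config.num_layers")
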