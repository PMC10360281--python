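"""Joint dual-channel pretraining: L = L_C + L_G.

Each optimization step encodes the full graphs for the contrastive channel
(fragment-attentive view vs atom-level readout, InfoNCE) and runs a second,
fragment-restricted pass for the masked-reconstruction channel; the two
losses are summed without weighting and optimized with Adam.  Weights are
Glorot-initialized; all randomness (initialization, shuffling, masking)
derives from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .contrastive import (
    AttentionParams,
    ContrastiveBatch,
    attentive_pool,
    fragment_mean_pool,
    infonce_loss,
    init_attention_params,
)
from .encoder import EncoderConfig, GraphBatch, encode, init_encoder_params
from .fragmentation import FragmentAssignment, brics_partition
from .generative import (
    GenerativeConfig,
    generative_loss,
    init_decoder_params,
    sample_mask,
)
from .mol_io import (
    NUM_ATOM_TYPE_SLOTS,
    NUM_BOND_DIRECTIONS,
    NUM_BOND_TYPE_SLOTS,
    NUM_CHIRALITY_TAGS,
    MolecularGraph,
)

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1

__all__ = ["PretrainConfig", "Checkpoint", "init_params", "pretrain"]


@dataclass
class PretrainConfig:
    batch_size: int = 256
    learning_rate: float = 0.001
    epochs: int = 100
    seed: int = 42
    tau: float = 0.1
    mask_ratio: float = 0.3
    gamma: float = 2.0
    attention_logit_mode: str = "per_fragment"
    remask_before_decode: bool = True
    grad_clip_norm: float | None = 5.0
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (InfoNCE needs a negative)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if isinstance(self.encoder, dict):
            self.encoder = EncoderConfig(**self.encoder)

    @property
    def generative(self) -> GenerativeConfig:
        return GenerativeConfig(
            mask_ratio=self.mask_ratio,
            gamma=self.gamma,
            remask_before_decode=self.remask_before_decode,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PretrainConfig":
        return cls(**d)


def _vocab() -> dict:
    return {
        "atom_type_slots": NUM_ATOM_TYPE_SLOTS,
        "chirality_tags": NUM_CHIRALITY_TAGS,
        "bond_type_slots": NUM_BOND_TYPE_SLOTS,
        "bond_directions": NUM_BOND_DIRECTIONS,
    }


@dataclass
class Checkpoint:
    """Config + featurization vocabulary + all weight tensors, versioned."""

    config: PretrainConfig
    params: dict[str, Tensor]
    vocab: dict = field(default_factory=_vocab)
    epoch: int = 0
    version: int = CHECKPOINT_VERSION

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = json.dumps(
            {
                "version": self.version,
                "epoch": self.epoch,
                "vocab": self.vocab,
                "config": self.config.to_dict(),
            }
        )
        arrays = {k.replace(".", "__"): p.data for k, p in self.params.items()}
        np.savez(path, __meta__=np.array(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["__meta__"]))
            params = {}
            for k in npz.files:
                if k == "__meta__":
                    continue
                name = k.replace("__", ".")
                if name.endswith((".norm_m", ".norm_v")):  # running buffers
                    params[name] = Tensor(npz[k])
                else:
                    params[name] = ad.parameter(npz[k])
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        return cls(
            config=PretrainConfig.from_dict(meta["config"]),
            params=params,
            vocab=meta["vocab"],
            epoch=meta["epoch"],
            version=meta["version"],
        )

    def attention_params(self) -> AttentionParams:
        return AttentionParams(
            w_q=self.params["attn.w_q"],
            w_k=self.params["attn.w_k"],
            w_v=self.params["attn.w_v"],
        )


def init_params(config: PretrainConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    """All trainable tensors: encoder, attention projections, decoder."""
    params = init_encoder_params(config.encoder, rng)
    params.update(init_attention_params(config.encoder.hidden_dim, rng))
    params.update(init_decoder_params(config.encoder, config.generative, rng))
    return params


def pretrain_step(
    graphs: list[MolecularGraph],
    assignments: list[FragmentAssignment],
    params: dict[str, Tensor],
    config: PretrainConfig,
    rng: np.random.Generator,
) -> tuple[Tensor, float, float]:
    """One forward pass over a batch; returns (L, L_C value, L_G value)."""
    batch = GraphBatch.from_graphs(graphs, assignments)
    # contrastive channel: full-graph pass
    node_emb, mol_emb = encode(batch, params, config.encoder, train=True)
    frag_emb = fragment_mean_pool(node_emb, batch.frag_of_atom, batch.num_frags)
    attn = AttentionParams(
        w_q=params["attn.w_q"], w_k=params["attn.w_k"], w_v=params["attn.w_v"]
    )
    frag_view = attentive_pool(
        frag_emb, batch.frag_mol, batch.num_mols, attn,
        logit_mode=config.attention_logit_mode,
    )
    l_c = infonce_loss(
        ContrastiveBatch(fragment_view=frag_view, atom_view=mol_emb,
                         temperature=config.tau)
    )
    # generative channel: fragment-restricted pass with shared encoder weights
    masks = [sample_mask(g, config.mask_ratio, rng) for g in graphs]
    l_g = generative_loss(batch, masks, params, config.encoder, config.generative,
                          train=True)
    return ad.add(l_c, l_g), l_c.item(), l_g.item()


def pretrain(
    library: list[MolecularGraph],
    config: PretrainConfig,
    log_path: str | Path | None = None,
) -> tuple[Checkpoint, list[dict]]:
    """Pretrain on an unlabeled molecule library.

    Molecules are fragmented once up front; per epoch the library is
    shuffled, split into batches (incomplete batches of size < 2 dropped),
    and the unweighted sum L_C + L_G is backpropagated.  Returns the final
    checkpoint and the per-epoch history of mean losses.
    """
    if not library:
        raise ValueError("empty pretraining library")
    assignments = [brics_partition(g) for g in library]

    rng = np.random.default_rng(config.seed)
    params = init_params(config, rng)
    opt = Adam(params, lr=config.learning_rate, clip_norm=config.grad_clip_norm)

    history: list[dict] = []
    log_file = open(log_path, "w") if log_path else None
    try:
        for epoch in range(1, config.epochs + 1):
            perm = rng.permutation(len(library))
            sums = np.zeros(3)
            n_steps = 0
            for start in range(0, len(library), config.batch_size):
                idx = perm[start:start + config.batch_size]
                if len(idx) < 2:
                    continue
                loss, l_c, l_g = pretrain_step(
                    [library[i] for i in idx],
                    [assignments[i] for i in idx],
                    params, config, rng,
                )
                total = loss.item()
                if not np.isfinite(total):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} (L_C={l_c}, L_G={l_g})"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                sums += (total, l_c, l_g)
                n_steps += 1
            rec = {
                "epoch": epoch,
                "steps": n_steps,
                "loss": float(sums[0]) / max(n_steps, 1),
                "loss_contrastive": float(sums[1]) / max(n_steps, 1),
                "loss_generative": float(sums[2]) / max(n_steps, 1),
            }
            history.append(rec)
            logger.info(
                "epoch %d: L=%.4f L_C=%.4f L_G=%.4f", epoch, rec["loss"],
                rec["loss_contrastive"], rec["loss_generative"],
            )
            if log_file:
                log_file.write(json.dumps(rec) + "\n")
                log_file.flush()
    finally:
        if log_file:
            log_file.close()
    ckpt = Checkpoint(config=config, params=params, epoch=config.epochs)
    return ckpt, history
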