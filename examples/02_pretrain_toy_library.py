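"""Pretrain the dual-channel model on a small generated molecule library.

Each optimization step combines the InfoNCE contrastive loss L_C (fragment-
attentive view vs atom-level readout) with the fragment-restricted masked
reconstruction loss L_G, and minimizes their unweighted sum L = L_C + L_G.
A small encoder keeps this demo fast; drop the `encoder=` override to train
at the default 5-layer / 300-dim setting.
"""

from fragssl import (
    EncoderConfig,
    PretrainConfig,
    ToyLibrarySpec,
    generate_library,
    parse_smiles,
    pretrain,
)

library = generate_library(ToyLibrarySpec(n_molecules=60, seed=0))
graphs = [parse_smiles(s) for s in library.smiles]

config = PretrainConfig(
    batch_size=20,
    epochs=8,
    seed=42,
    encoder=EncoderConfig(num_layers=3, hidden_dim=64),
)
checkpoint, history = pretrain(graphs, config)

print(f"pretrained on {len(graphs)} molecules")
for rec in history:
    print(
        f"epoch {rec['epoch']:2d}: L = {rec['loss']:.4f} "
        f"(contrastive {rec['loss_contrastive']:.4f}, "
        f"generative {rec['loss_generative']:.4f})"
    )
checkpoint.save("scratch_toy_checkpoint.npz")
print("checkpoint written to scratch_toy_checkpoint.npz")

# The total loss should fall over the epochs: the contrastive term learns to
# match each molecule's two views against in-batch negatives, while the
# generative term learns to reconstruct masked atom-feature embeddings from
# intra-fragment context.
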