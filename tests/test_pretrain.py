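"""Joint pretraining: loss composition, gradients, determinism, checkpoints."""

import json

import numpy as np
import pytest

import fragssl.autodiff as ad
from fragssl.contrastive import AttentionParams, ContrastiveBatch, attentive_pool, fragment_mean_pool, infonce_loss
from fragssl.encoder import EncoderConfig, GraphBatch, encode
from fragssl.fragmentation import brics_partition
from fragssl.generative import MaskSpec, generative_loss
from fragssl.mol_io import parse_smiles
from fragssl.pretrain import Checkpoint, PretrainConfig, init_params, pretrain, pretrain_step


def _fixed_loss(params, batch, masks, config, frozen_target=None):
    """Deterministic forward pass of L = L_C + L_G with fixed masks.

    ``frozen_target`` substitutes a fixed reconstruction-target matrix; the
    training loss treats targets as constants (stop-gradient), so the
    finite-difference check must hold them fixed too.
    """
    from fragssl.generative import reconstruct_batch, scaled_cosine_error

    node_emb, mol_emb = encode(batch, params, config.encoder)
    frag_emb = fragment_mean_pool(node_emb, batch.frag_of_atom, batch.num_frags)
    attn = AttentionParams(params["attn.w_q"], params["attn.w_k"], params["attn.w_v"])
    frag_view = attentive_pool(frag_emb, batch.frag_mol, batch.num_mols, attn)
    l_c = infonce_loss(ContrastiveBatch(frag_view, mol_emb, config.tau))
    recon, target, mol_of = reconstruct_batch(
        batch, masks, params, config.encoder, config.generative
    )
    t = target if frozen_target is None else ad.constant(frozen_target)
    l_g = scaled_cosine_error(t, recon, mol_of, batch.num_mols, config.gamma)
    return l_c, l_g


@pytest.fixture
def two_mol_setup():
    config = PretrainConfig(
        batch_size=2, seed=7, encoder=EncoderConfig(num_layers=2, hidden_dim=4)
    )
    graphs = [parse_smiles("CCOC(=O)c1ccccc1"), parse_smiles("CC(=O)NCC")]
    assignments = [brics_partition(g) for g in graphs]
    batch = GraphBatch.from_graphs(graphs, assignments)
    masks = [
        MaskSpec(masked_atoms=np.array([0, 4]), mask_ratio=0.2),
        MaskSpec(masked_atoms=np.array([2]), mask_ratio=0.2),
    ]
    params = init_params(config, np.random.default_rng(7))
    return config, batch, masks, params


def test_total_loss_is_exact_sum_of_channels(two_mol_setup):
    config, batch, masks, params = two_mol_setup
    l_c, l_g = _fixed_loss(params, batch, masks, config)
    total = ad.add(l_c, l_g)
    assert total.item() == l_c.item() + l_g.item()


def test_gradient_matches_finite_differences(two_mol_setup):
    """Analytic gradient of L on a 2-molecule batch vs central differences."""
    config, batch, masks, params = two_mol_setup
    from fragssl.generative import reconstruct_batch

    _, target0, _ = reconstruct_batch(batch, masks, params, config.encoder, config.generative)
    frozen = target0.data.copy()

    def loss_value():
        l_c, l_g = _fixed_loss(params, batch, masks, config, frozen_target=frozen)
        return l_c.item() + l_g.item()

    l_c, l_g = _fixed_loss(params, batch, masks, config, frozen_target=frozen)
    total = ad.add(l_c, l_g)
    for p in params.values():
        p.grad = None
    total.backward()

    eps = 1e-6
    rng = np.random.default_rng(0)
    checked = 0
    for name, p in params.items():
        if p.grad is None:
            continue
        flat = p.data.reshape(-1)
        gflat = p.grad.reshape(-1)
        n_coords = min(4, flat.size)
        for i in rng.choice(flat.size, size=n_coords, replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            fp = loss_value()
            flat[i] = orig - eps
            fm = loss_value()
            flat[i] = orig
            num = (fp - fm) / (2 * eps)
            if abs(num) < 1e-8 and abs(gflat[i]) < 1e-8:
                continue
            assert abs(num - gflat[i]) <= 1e-4 * max(abs(num), abs(gflat[i]), 1e-3), (
                f"{name}[{i}]: analytic {gflat[i]} vs numeric {num}"
            )
            checked += 1
    assert checked > 50


def test_step_count_and_history(tmp_path):
    config = PretrainConfig(
        batch_size=2, epochs=1, seed=1, encoder=EncoderConfig(num_layers=1, hidden_dim=6)
    )
    graphs = [parse_smiles(s) for s in ["CCO", "CCN", "CCC", "c1ccccc1"]]
    log = tmp_path / "log.jsonl"
    _, history = pretrain(graphs, config, log_path=log)
    assert history[0]["steps"] == 2      # 4 molecules / batch 2
    lines = [json.loads(l) for l in log.read_text().splitlines()]
    assert len(lines) == 1 and lines[0]["epoch"] == 1


def test_incomplete_batch_below_two_dropped():
    config = PretrainConfig(
        batch_size=2, epochs=1, seed=1, encoder=EncoderConfig(num_layers=1, hidden_dim=6)
    )
    graphs = [parse_smiles(s) for s in ["CCO", "CCN", "CCC"]]
    _, history = pretrain(graphs, config)
    assert history[0]["steps"] == 1      # trailing singleton dropped


def test_same_seed_reproduces_final_loss():
    config = PretrainConfig(
        batch_size=4, epochs=3, seed=99, encoder=EncoderConfig(num_layers=2, hidden_dim=8)
    )
    graphs = [parse_smiles(s) for s in
              ["CCOC(=O)c1ccccc1", "CC(=O)NCC", "c1ccc(OCC)cc1", "C1CCC(C(=O)NC)CC1",
               "CCCCC(=O)OC", "c1ccc(CCN)cc1"]]
    _, h1 = pretrain(graphs, config)
    _, h2 = pretrain(graphs, config)
    assert abs(h1[-1]["loss"] - h2[-1]["loss"]) < 1e-12


def test_short_training_decreases_loss(toy_graphs):
    config = PretrainConfig(
        batch_size=10, epochs=5, seed=3,
        encoder=EncoderConfig(num_layers=2, hidden_dim=16),
    )
    _, history = pretrain(toy_graphs[:30], config)
    assert history[-1]["loss"] < history[0]["loss"]


def test_empty_library_rejected():
    with pytest.raises(ValueError):
        pretrain([], PretrainConfig())


def test_checkpoint_round_trip_bit_for_bit(tmp_path, toy_graphs):
    config = PretrainConfig(
        batch_size=8, epochs=1, seed=5, encoder=EncoderConfig(num_layers=2, hidden_dim=8)
    )
    ckpt, _ = pretrain(toy_graphs[:16], config)
    path = tmp_path / "ckpt.npz"
    ckpt.save(path)
    loaded = Checkpoint.load(path)
    assert loaded.config == ckpt.config
    assert loaded.vocab == ckpt.vocab
    batch = GraphBatch.from_graphs(toy_graphs[:4])
    _, hg_a = encode(batch, ckpt.params, config.encoder)
    _, hg_b = encode(batch, loaded.params, loaded.config.encoder)
    assert (hg_a.data == hg_b.data).all()


def test_config_validation():
    with pytest.raises(ValueError):
        PretrainConfig(batch_size=1)
    with pytest.raises(ValueError):
        PretrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        PretrainConfig(tau=0.0)
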