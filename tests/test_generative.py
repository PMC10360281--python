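"""Masked autoencoding channel: mask sampling, reconstruction, scaled cosine error."""

import numpy as np
import pytest

import fragssl.autodiff as ad
from fragssl.autodiff import Adam
from fragssl.encoder import EncoderConfig, GraphBatch
from fragssl.fragmentation import brics_partition
from fragssl.generative import (
    GenerativeConfig,
    generative_loss,
    init_decoder_params,
    reconstruct_batch,
    sample_mask,
    scaled_cosine_error,
)
from fragssl.mol_io import ATOM_MASK_INDEX, parse_smiles
from fragssl.pretrain import PretrainConfig, init_params

from oracles import masked_reconstruct_oracle, scaled_cosine_error_oracle

RNG = np.random.default_rng(31)


class TestSampleMask:
    def test_floor_rule(self):
        g = parse_smiles("C" * 10)
        m = sample_mask(g, 0.3, np.random.default_rng(0))
        assert len(m.masked_atoms) == 3

    def test_minimum_one_atom_when_two_or_more(self):
        g = parse_smiles("CC")
        m = sample_mask(g, 0.01, np.random.default_rng(0))
        assert len(m.masked_atoms) == 1

    def test_single_atom_molecule_gets_empty_mask(self):
        g = parse_smiles("C")
        m = sample_mask(g, 0.3, np.random.default_rng(0))
        assert len(m.masked_atoms) == 0

    def test_deterministic_under_seed(self):
        g = parse_smiles("CCOC(=O)c1ccccc1")
        a = sample_mask(g, 0.4, np.random.default_rng(5))
        b = sample_mask(g, 0.4, np.random.default_rng(5))
        np.testing.assert_array_equal(a.masked_atoms, b.masked_atoms)

    @pytest.mark.parametrize("ratio", [0.0, 1.0, -0.1])
    def test_invalid_ratio_rejected(self, ratio):
        with pytest.raises(ValueError):
            sample_mask(parse_smiles("CC"), ratio, np.random.default_rng(0))


class TestScaledCosineError:
    def test_equal_vectors_zero(self):
        x = RNG.normal(size=(4, 3))
        loss = scaled_cosine_error(x, x.copy(), np.zeros(4, dtype=int), 1, 2.0)
        np.testing.assert_allclose(loss.item(), 0.0, atol=1e-12)

    @pytest.mark.parametrize("gamma", [1.0, 2.0, 3.0])
    def test_orthogonal_vectors_one(self, gamma):
        t = np.array([[1.0, 0.0], [0.0, 2.0]])
        z = np.array([[0.0, 3.0], [-1.0, 0.0]])
        loss = scaled_cosine_error(t, z, np.zeros(2, dtype=int), 1, gamma)
        np.testing.assert_allclose(loss.item(), 1.0, rtol=1e-12)

    @pytest.mark.parametrize("gamma", [1.0, 2.0, 3.0])
    def test_antiparallel_vectors_two_to_gamma(self, gamma):
        t = RNG.normal(size=(3, 4))
        loss = scaled_cosine_error(t, -t, np.zeros(3, dtype=int), 1, gamma)
        np.testing.assert_allclose(loss.item(), 2.0 ** gamma, rtol=1e-12)

    def test_invariant_to_positive_rescaling(self):
        t = RNG.normal(size=(5, 3))
        z = RNG.normal(size=(5, 3))
        mol = np.array([0, 0, 1, 1, 1])
        a = scaled_cosine_error(t, z, mol, 2, 2.0).item()
        b = scaled_cosine_error(t * 7.5, z * 0.03, mol, 2, 2.0).item()
        np.testing.assert_allclose(a, b, rtol=1e-8)  # up to the eps norm guard

    def test_bounds_and_oracle_agreement(self):
        t = RNG.normal(size=(6, 4))
        z = RNG.normal(size=(6, 4))
        mol = np.array([0, 0, 0, 1, 1, 2])
        got = scaled_cosine_error(t, z, mol, 3, 2.0).item()
        want = scaled_cosine_error_oracle(t, z, mol, 3, 2.0)
        np.testing.assert_allclose(got, want, rtol=1e-10)
        assert 0.0 <= got <= 2.0 ** 2.0

    def test_zero_norm_target_rejected(self):
        t = np.array([[0.0, 0.0], [1.0, 0.0]])
        z = RNG.normal(size=(2, 2))
        with pytest.raises(FloatingPointError):
            scaled_cosine_error(t, z, np.zeros(2, dtype=int), 1, 2.0)


def _setup(smiles, seed=0, hidden=6, layers=2):
    cfg = PretrainConfig(
        batch_size=2, seed=seed,
        encoder=EncoderConfig(num_layers=layers, hidden_dim=hidden),
    )
    params = init_params(cfg, np.random.default_rng(seed))
    graphs = [parse_smiles(s) for s in smiles]
    assignments = [brics_partition(g) for g in graphs]
    batch = GraphBatch.from_graphs(graphs, assignments)
    return cfg, params, graphs, assignments, batch


class TestReconstruct:
    def test_matches_scalar_oracle_single_fragment(self):
        """3-atom single-fragment molecule, 1 masked atom: brute-force check."""
        cfg, params, graphs, _, batch = _setup(["CCO"], hidden=5, layers=2)
        from fragssl.generative import MaskSpec

        mask = MaskSpec(masked_atoms=np.array([1]), mask_ratio=0.34)
        recon, target, mol_of = reconstruct_batch(
            batch, [mask], params, cfg.encoder, cfg.generative
        )
        pnp = {k: p.data for k, p in params.items()}
        want = masked_reconstruct_oracle(graphs[0], pnp, 2, [1], ATOM_MASK_INDEX)
        np.testing.assert_allclose(recon.data, want, rtol=1e-9, atol=1e-12)
        # target is the clean embedded feature of the masked atom
        feats = graphs[0].atom_features[1]
        np.testing.assert_allclose(
            target.data[0],
            pnp["atom_emb_type"][feats[0]] + pnp["atom_emb_chir"][feats[1]],
        )

    def test_zero_masked_atoms_gives_zero_loss(self):
        cfg, params, _, _, batch = _setup(["C", "C"])
        from fragssl.generative import MaskSpec

        masks = [MaskSpec(masked_atoms=np.zeros(0, dtype=np.int64), mask_ratio=0.3)] * 2
        loss = generative_loss(batch, masks, params, cfg.encoder, cfg.generative)
        assert loss.item() == 0.0

    def test_reconstruction_confined_to_fragment(self):
        """Perturbing atom features in *other* fragments leaves a masked
        atom's reconstruction exactly unchanged."""
        smiles = "CCOC(=O)c1ccccc1"  # >= 2 BRICS fragments
        cfg, params, graphs, assignments, batch = _setup([smiles])
        fa = assignments[0]
        assert fa.num_fragments >= 2
        # mask one atom of fragment 0
        target_atom = int(fa.atoms_of(0)[0])
        from fragssl.generative import MaskSpec

        mask = MaskSpec(masked_atoms=np.array([target_atom]), mask_ratio=0.1)
        recon_a, _, _ = reconstruct_batch(batch, [mask], params, cfg.encoder, cfg.generative)

        g2 = parse_smiles(smiles)
        other = fa.atoms_of(fa.num_fragments - 1)
        g2.atom_features[other, 0] = 14  # carbon -> phosphorus elsewhere
        batch2 = GraphBatch.from_graphs([g2], [fa])
        recon_b, _, _ = reconstruct_batch(batch2, [mask], params, cfg.encoder, cfg.generative)
        assert (recon_a.data == recon_b.data).all()

    def test_overfit_single_molecule_drives_loss_down(self):
        """A fixed molecule and mask can be memorized in a few hundred steps."""
        cfg, params, graphs, assignments, batch = _setup(
            ["CCOC(=O)c1ccccc1"], hidden=16, layers=2
        )
        from fragssl.generative import MaskSpec

        mask = MaskSpec(masked_atoms=np.array([1, 5]), mask_ratio=0.2)
        opt = Adam(params, lr=0.01)
        losses = []
        for _ in range(500):
            loss = generative_loss(batch, [mask], params, cfg.encoder, cfg.generative)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        assert losses[-1] < 0.01
        assert losses[-1] < losses[0]


def test_generative_config_validation():
    with pytest.raises(ValueError):
        GenerativeConfig(mask_ratio=0.0)
    with pytest.raises(ValueError):
        GenerativeConfig(gamma=0.5)
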