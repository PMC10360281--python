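"""Independent brute-force oracles used by the tests.

Everything here is written as plain scalar/loop NumPy, deliberately not
sharing code paths with the package's vectorized implementation, so that
agreement between the two is a meaningful check.
"""

from __future__ import annotations

import numpy as np


def _neighbor_lists(graph):
    nbrs = {v: [] for v in range(graph.num_atoms)}
    for (u, v), (bt, bd) in zip(graph.bond_list, graph.bond_features):
        nbrs[int(u)].append((int(v), int(bt), int(bd)))
        nbrs[int(v)].append((int(u), int(bt), int(bd)))
    return nbrs


def gin_layer_oracle(h, nbrs, layer, final_relu, norm="batch"):
    """Loop-based single GIN layer; ``layer`` maps short names to arrays.

    ``norm="batch"`` applies eval-mode batch normalization with the stored
    running statistics; ``norm="layer"`` normalizes each node over features.
    """
    n = len(h)
    et, ed = layer["edge_emb_type"], layer["edge_emb_dir"]
    new_h = np.zeros_like(h)
    for v in range(n):
        agg = h[v] + et[4] + ed[0]  # self-loop slot
        for u, bt, bd in nbrs[v]:
            agg = agg + h[u] + et[bt] + ed[bd]
        z = np.maximum(agg @ layer["w1"] + layer["b1"], 0.0) @ layer["w2"] + layer["b2"]
        if norm == "batch":
            z = (z - layer["norm_m"]) / np.sqrt(layer["norm_v"] + 1e-5)
        else:
            mu = z.mean()
            var = ((z - mu) ** 2).mean()
            z = (z - mu) / np.sqrt(var + 1e-5)
        z = z * layer["norm_g"] + layer["norm_b"]
        if final_relu:
            z = np.maximum(z, 0.0)
        new_h[v] = z
    return new_h


def _layer(params, prefix):
    names = ("edge_emb_type", "edge_emb_dir", "w1", "b1", "w2", "b2",
             "norm_g", "norm_b", "norm_m", "norm_v")
    return {n: params[f"{prefix}.{n}"] for n in names}


def gin_encode_oracle(graph, params, num_layers, readout="mean",
                      atom_features=None, norm="batch"):
    """Loop-based re-evaluation of the encoder forward pass.

    ``params`` maps the package's parameter names to raw ndarrays;
    ``atom_features`` optionally substitutes corrupted (type, chirality)
    index arrays.
    """
    feats = graph.atom_features if atom_features is None else np.stack(atom_features, axis=1)
    n = graph.num_atoms
    h = np.array([params["atom_emb_type"][feats[v, 0]] + params["atom_emb_chir"][feats[v, 1]]
                  for v in range(n)])
    nbrs = _neighbor_lists(graph)
    for k in range(num_layers):
        h = gin_layer_oracle(h, nbrs, _layer(params, f"enc.{k}"),
                             final_relu=(k < num_layers - 1), norm=norm)
    hg = h.mean(axis=0) if readout == "mean" else h.sum(axis=0)
    return h, hg


def masked_reconstruct_oracle(graph, params, num_layers, masked, mask_index,
                              remask=True):
    """Loop-based masked reconstruction for a single-fragment molecule
    (all bonds intra-fragment): corrupt, encode, re-mask, decode, project."""
    types = graph.atom_features[:, 0].copy()
    chirs = graph.atom_features[:, 1].copy()
    types[masked] = mask_index
    chirs[masked] = 0
    h, _ = gin_encode_oracle(graph, params, num_layers, atom_features=(types, chirs))
    if remask:
        for v in masked:
            h[v] = params["dec.mask_token"][0]
    h = gin_layer_oracle(h, _neighbor_lists(graph), _layer(params, "dec.0"),
                         final_relu=False, norm="batch")
    z = h @ params["dec.out_w"] + params["dec.out_b"]
    return z[masked]


def attention_pool_oracle(frag_embs, w_q, w_k, w_v):
    """Scalar evaluation of scaled-dot-product fragment attention for one
    molecule: logits q.k/sqrt(D), softmax over fragments, weighted values."""
    d = frag_embs.shape[1]
    logits = []
    values = []
    for f in frag_embs:
        q, k, v = f @ w_q, f @ w_k, f @ w_v
        logits.append(float(np.dot(q, k)) / np.sqrt(d))
        values.append(v)
    logits = np.array(logits)
    w = np.exp(logits - logits.max())
    w = w / w.sum()
    out = np.zeros(d)
    for wi, vi in zip(w, values):
        out += wi * vi
    return out, w


def infonce_oracle(anchors, positives, tau):
    """Direct scalar evaluation of the InfoNCE objective with cosine critic."""
    b = len(anchors)
    total = 0.0
    for i in range(b):
        def cos(x, y):
            return float(np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y)))
        num = np.exp(cos(anchors[i], positives[i]) / tau)
        den = sum(np.exp(cos(anchors[i], positives[j]) / tau) for j in range(b))
        total += -np.log(num / den)
    return total / b


def scaled_cosine_error_oracle(targets, recons, mol_of_masked, num_mols, gamma):
    """Scalar evaluation of the per-molecule-averaged scaled cosine error."""
    per_mol = np.zeros(num_mols)
    counts = np.zeros(num_mols)
    for t, z, m in zip(targets, recons, mol_of_masked):
        c = float(np.dot(t, z) / (np.linalg.norm(t) * np.linalg.norm(z)))
        per_mol[m] += (1.0 - c) ** gamma
        counts[m] += 1
    out = 0.0
    for m in range(num_mols):
        if counts[m]:
            out += per_mol[m] / counts[m]
    return out / num_mols


def pairwise_auc_oracle(labels, scores):
    """AUC as the fraction of concordant positive/negative pairs (ties 1/2)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
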