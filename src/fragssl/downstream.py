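"""Downstream evaluation: scaffold splitting, fine-tuning, metrics.

Scaffold splitting groups molecules by Bemis-Murcko scaffold and assigns
whole groups (largest first) to train/validation/test, which simulates
generalization to unseen chemotypes.  Fine-tuning puts a linear task head on
the pooled molecule embedding and updates encoder and head jointly; the
epoch with the best validation metric is reported on the test split.
Classification uses per-task ROC-AUC with missing labels excluded;
regression uses RMSE.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.metrics import roc_auc_score

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .encoder import GraphBatch, encode
from .mol_io import LabeledDataset, MolecularGraph
from .pretrain import Checkpoint

logger = logging.getLogger(__name__)

__all__ = [
    "ScaffoldSplit",
    "MetricResult",
    "MetricUndefinedError",
    "scaffold_split",
    "murcko_scaffold",
    "roc_auc",
    "rmse",
    "finetune",
    "linear_probe",
    "embed",
    "evaluate_seeds",
]


class MetricUndefinedError(ValueError):
    """Raised when a metric is undefined (e.g. single-class ROC-AUC input)."""


@dataclass
class ScaffoldSplit:
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray

    def validate(self, n: int) -> None:
        allidx = np.concatenate([self.train, self.valid, self.test])
        if len(allidx) != n or len(np.unique(allidx)) != n:
            raise ValueError("splits must be disjoint and cover all molecules")


@dataclass
class MetricResult:
    metric: str                      # "roc_auc" | "rmse"
    per_task: np.ndarray             # values for the tasks that were scorable
    mean: float
    std: float = float("nan")        # across seeds, when aggregated

    @classmethod
    def from_values(cls, metric: str, per_task: np.ndarray) -> "MetricResult":
        return cls(metric=metric, per_task=per_task, mean=float(np.mean(per_task)))


def murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko scaffold SMILES; ring-free molecules share ''."""
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles, includeChirality=False)


def scaffold_split(
    dataset: LabeledDataset | list[str],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> ScaffoldSplit:
    """Group molecules by scaffold and assign whole groups greedily.

    Groups are ordered by descending size (ties by first occurrence) and
    filled into train until it holds at least ``ratios[0]`` of the
    molecules, then into validation until it holds ``ratios[1]``, remainder
    into test.  No scaffold ever spans two subsets.
    """
    smiles = dataset.smiles if isinstance(dataset, LabeledDataset) else list(dataset)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(smiles):
        groups.setdefault(murcko_scaffold(s), []).append(i)
    ordered = sorted(groups.values(), key=lambda idx: (-len(idx), idx[0]))

    n = len(smiles)
    n_train, n_valid = ratios[0] * n, ratios[1] * n
    train: list[int] = []
    valid: list[int] = []
    test: list[int] = []
    for grp in ordered:
        if len(train) < n_train:
            train.extend(grp)
        elif len(valid) < n_valid:
            valid.extend(grp)
        else:
            test.extend(grp)
    if not valid or not test:
        warnings.warn(
            "scaffold split produced an empty validation or test subset "
            "(too few scaffold groups for the requested ratios)",
            stacklevel=2,
        )
    split = ScaffoldSplit(
        train=np.asarray(train, dtype=np.int64),
        valid=np.asarray(valid, dtype=np.int64),
        test=np.asarray(test, dtype=np.int64),
    )
    split.validate(n)
    return split


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based ROC-AUC (ties count 1/2); requires both classes present."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise MetricUndefinedError("ROC-AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def rmse(labels: np.ndarray, predictions: np.ndarray) -> float:
    labels = np.asarray(labels, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if labels.shape != predictions.shape or labels.size == 0:
        raise ValueError("rmse needs equal-length, non-empty inputs")
    return float(np.sqrt(np.mean((labels - predictions) ** 2)))


def _score_tasks(
    labels: np.ndarray, preds: np.ndarray, task_kind: str
) -> MetricResult:
    """Per-task metric over non-missing entries; single-class tasks skipped."""
    vals = []
    for t in range(labels.shape[1]):
        ok = ~np.isnan(labels[:, t])
        if not ok.any():
            continue
        if task_kind == "classification":
            try:
                vals.append(roc_auc(labels[ok, t], preds[ok, t]))
            except MetricUndefinedError:
                logger.warning("task %d skipped: single-class labels", t)
        else:
            vals.append(rmse(labels[ok, t], preds[ok, t]))
    if not vals:
        raise MetricUndefinedError("no scorable task in this split")
    name = "roc_auc" if task_kind == "classification" else "rmse"
    return MetricResult.from_values(name, np.asarray(vals))


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def embed(checkpoint: Checkpoint, graphs: list[MolecularGraph]) -> np.ndarray:
    """Eval-mode molecule embeddings h_g (n_molecules x D)."""
    out = []
    bs = 256
    for start in range(0, len(graphs), bs):
        batch = GraphBatch.from_graphs(graphs[start:start + bs])
        _, hg = encode(batch, checkpoint.params, checkpoint.config.encoder)
        out.append(hg.data)
    return np.vstack(out)


def _clone_params(params: dict[str, Tensor]) -> dict[str, Tensor]:
    return {k: ad.parameter(p.data.copy()) for k, p in params.items()}


def finetune(
    checkpoint: Checkpoint,
    dataset: LabeledDataset,
    split: ScaffoldSplit,
    seed: int = 0,
    epochs: int = 100,
    learning_rate: float = 0.001,
    batch_size: int = 32,
    dropout: float = 0.5,
    freeze_encoder: bool = False,
) -> tuple[dict[str, Tensor], MetricResult]:
    """Fine-tune encoder + linear head on a labeled dataset.

    Classification minimizes per-task sigmoid cross-entropy with missing
    labels excluded; regression minimizes squared error.  The model state at
    the best validation epoch is evaluated on the test split.
    """
    if len(split.valid) == 0:
        raise ValueError("empty validation split; adjust ratios or dataset")
    import dataclasses as _dc

    rng = np.random.default_rng(seed)
    params = _clone_params(checkpoint.params)
    d = checkpoint.config.encoder.hidden_dim
    n_tasks = dataset.num_tasks
    params["head.w"] = ad.parameter(ad.glorot(rng, (d, n_tasks)))
    params["head.b"] = ad.parameter(np.zeros(n_tasks))
    enc_cfg = _dc.replace(checkpoint.config.encoder, dropout=dropout)
    eval_cfg = _dc.replace(checkpoint.config.encoder, dropout=0.0)

    trainable = (
        {k: v for k, v in params.items() if k.startswith("head.")}
        if freeze_encoder
        else {k: v for k, v in params.items()
              if k.startswith(("head.", "enc.", "atom_emb"))}
    )
    opt = Adam(trainable, lr=learning_rate)
    graphs = dataset.graphs
    labels = dataset.labels

    def predict(idx: np.ndarray) -> np.ndarray:
        preds = []
        for start in range(0, len(idx), 256):
            sub = idx[start:start + 256]
            b = GraphBatch.from_graphs([graphs[i] for i in sub])
            _, hg = encode(b, params, eval_cfg)
            preds.append(ad.linear(hg, params["head.w"], params["head.b"]).data)
        return np.vstack(preds)

    better = (lambda a, b: a > b) if dataset.task_kind == "classification" else (lambda a, b: a < b)
    best_val = None
    best_state = None
    for _epoch in range(epochs):
        order = rng.permutation(split.train)
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            b = GraphBatch.from_graphs([graphs[i] for i in idx])
            _, hg = encode(b, params, enc_cfg, train=True, rng=rng)
            logits = ad.linear(hg, params["head.w"], params["head.b"])
            y = labels[idx]
            mask = ~np.isnan(y)
            if not mask.any():
                continue
            yv = np.nan_to_num(y)
            m = mask.astype(float)
            if dataset.task_kind == "classification":
                # max(z,0) - y z + log(1 + e^-|z|): stable sigmoid cross-entropy
                z = logits
                neg_abs = ad.mul(ad.add(ad.relu(z), ad.relu(ad.mul(z, -1.0))), -1.0)
                soft = ad.add(ad.relu(z), ad.log(ad.add(1.0, ad.exp(neg_abs))))
                loss_el = ad.add(soft, ad.mul(ad.mul(z, yv), -1.0))
            else:
                diff = ad.add(logits, -yv)
                loss_el = ad.mul(diff, diff)
            loss = ad.mul(ad.tsum(ad.mul(loss_el, m)), 1.0 / m.sum())
            if not np.isfinite(loss.item()):
                raise RuntimeError("non-finite fine-tuning loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
        val_metric = _score_tasks(labels[split.valid], predict(split.valid),
                                  dataset.task_kind)
        if best_val is None or better(val_metric.mean, best_val):
            best_val = val_metric.mean
            best_state = {k: v.data.copy() for k, v in params.items()}
    for k, v in best_state.items():
        params[k].data = v
    if len(split.test):
        result = _score_tasks(labels[split.test], predict(split.test),
                              dataset.task_kind)
    else:
        warnings.warn("empty test split; reporting validation metric", stacklevel=2)
        result = _score_tasks(labels[split.valid], predict(split.valid),
                              dataset.task_kind)
    return params, result


def linear_probe(
    checkpoint: Checkpoint,
    dataset: LabeledDataset,
    split: ScaffoldSplit,
    seed: int = 0,
) -> MetricResult:
    """Freeze the encoder and fit a linear head per task in closed/convex form.

    Regression tasks use ordinary least squares; classification tasks use
    logistic regression.  This isolates how linearly decodable the labels
    are from the pretrained embeddings, without fine-tuning dynamics.
    """
    from sklearn.linear_model import LinearRegression, LogisticRegression

    emb = embed(checkpoint, dataset.graphs)
    labels = dataset.labels
    test_idx = split.test if len(split.test) else split.valid
    if len(test_idx) == 0:
        raise ValueError("probe needs a non-empty test (or validation) subset")
    vals = []
    for t in range(dataset.num_tasks):
        ok_tr = split.train[~np.isnan(labels[split.train, t])]
        ok_te = test_idx[~np.isnan(labels[test_idx, t])]
        if len(ok_tr) == 0 or len(ok_te) == 0:
            continue
        if dataset.task_kind == "classification":
            if len(np.unique(labels[ok_tr, t])) < 2:
                logger.warning("probe task %d skipped: single-class train labels", t)
                continue
            clf = LogisticRegression(max_iter=2000, random_state=seed)
            clf.fit(emb[ok_tr], labels[ok_tr, t])
            scores = clf.decision_function(emb[ok_te])
            try:
                vals.append(roc_auc(labels[ok_te, t], scores))
            except MetricUndefinedError:
                logger.warning("probe task %d skipped: single-class test labels", t)
        else:
            reg = LinearRegression()
            reg.fit(emb[ok_tr], labels[ok_tr, t])
            vals.append(rmse(labels[ok_te, t], reg.predict(emb[ok_te])))
    if not vals:
        raise MetricUndefinedError("no scorable task for the probe")
    name = "roc_auc" if dataset.task_kind == "classification" else "rmse"
    return MetricResult.from_values(name, np.asarray(vals))


def evaluate_seeds(
    checkpoint: Checkpoint,
    dataset: LabeledDataset,
    seeds: list[int],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    **finetune_kwargs,
) -> MetricResult:
    """Repeat fine-tuning over seeds and report mean +/- std of the metric."""
    means = []
    per_task = []
    for s in seeds:
        split = scaffold_split(dataset, ratios)
        _, res = finetune(checkpoint, dataset, split, seed=s, **finetune_kwargs)
        means.append(res.mean)
        per_task.append(res.per_task)
    return MetricResult(
        metric="roc_auc" if dataset.task_kind == "classification" else "rmse",
        per_task=np.mean(per_task, axis=0),
        mean=float(np.mean(means)),
        std=float(np.std(means)),
    )
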