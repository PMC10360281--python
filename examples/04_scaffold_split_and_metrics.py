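"""Scaffold splitting and the evaluation metrics on worked examples.

Scaffold splits assign whole Bemis-Murcko scaffold groups to train /
validation / test, so the test set contains chemotypes never seen in
training — the out-of-distribution protocol used for molecular property
benchmarks.
"""

import numpy as np

from fragssl import ToyLibrarySpec, generate_library, rmse, roc_auc, scaffold_split
from fragssl.downstream import murcko_scaffold

library = generate_library(ToyLibrarySpec(n_molecules=50, seed=3))
split = scaffold_split(library.smiles.tolist())
print(f"{len(split.train)} train / {len(split.valid)} valid / {len(split.test)} test")

train_scaffolds = {murcko_scaffold(library.smiles[i]) for i in split.train}
test_scaffolds = {murcko_scaffold(library.smiles[i]) for i in split.test}
print("scaffolds shared between train and test:", train_scaffolds & test_scaffolds)

# ROC-AUC on a 4-point example: 3 of the 4 positive/negative score pairs are
# concordant, so AUC = 3/4.
labels = np.array([1, 0, 1, 0])
scores = np.array([0.9, 0.8, 0.7, 0.1])
print("ROC-AUC:", roc_auc(labels, scores))

# RMSE on a 3-point example: errors (1, 0, 1) give sqrt(2/3) ~ 0.8165.
print("RMSE:", rmse(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0])))
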