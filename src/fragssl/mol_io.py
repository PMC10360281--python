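"""SMILES parsing and molecular-graph featurization.

Molecules are represented as undirected graphs over heavy atoms.  Each atom
carries a pair of categorical features (atom-type index derived from the
atomic number, chirality-tag index) and each bond a pair (bond-type index,
bond-direction index), following the widely used pretraining featurization
convention for molecular GNNs.  Vocabulary sizes are fixed module constants
and are stored in checkpoints so embedding tables are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

# Feature vocabulary (fixed at construction; recorded in checkpoints).
NUM_ATOM_TYPES = 120          # atomic numbers 1..119 -> indices 0..118
ATOM_MASK_INDEX = 120         # reserved [MASK] slot appended after the vocabulary
NUM_ATOM_TYPE_SLOTS = NUM_ATOM_TYPES + 1
NUM_CHIRALITY_TAGS = 3        # unspecified / CW / CCW (other -> unspecified)
NUM_BOND_TYPES = 4            # single / double / triple / aromatic
BOND_SELF_LOOP_INDEX = 4      # extra slot used for self-loop edges
NUM_BOND_TYPE_SLOTS = NUM_BOND_TYPES + 1
NUM_BOND_DIRECTIONS = 3       # none / end-up-right / end-down-right

_CHIRALITY_MAP = {
    Chem.ChiralType.CHI_UNSPECIFIED: 0,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: 1,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: 2,
}
_BOND_TYPE_MAP = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}
_BOND_DIR_MAP = {
    Chem.BondDir.NONE: 0,
    Chem.BondDir.ENDUPRIGHT: 1,
    Chem.BondDir.ENDDOWNRIGHT: 2,
}


class SmilesParseError(ValueError):
    """Raised for SMILES that RDKit cannot sanitize; carries the string."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass
class MolecularGraph:
    """A featurized heavy-atom molecular graph G = (V, E).

    Bonds are stored once (undirected); message passing expands them to both
    directions internally.
    """

    num_atoms: int
    atom_features: np.ndarray      # (num_atoms, 2) int: (type index, chirality)
    bond_list: np.ndarray          # (num_bonds, 2) int, each undirected bond once
    bond_features: np.ndarray      # (num_bonds, 2) int: (bond type, direction)
    smiles: str = ""

    @property
    def num_bonds(self) -> int:
        return len(self.bond_list)

    def validate(self) -> None:
        if self.atom_features.shape != (self.num_atoms, 2):
            raise ValueError("atom_features shape mismatch")
        if self.bond_features.shape != (len(self.bond_list), 2):
            raise ValueError("bond_features shape mismatch")
        if self.num_bonds:
            if self.bond_list.min() < 0 or self.bond_list.max() >= self.num_atoms:
                raise ValueError("bond endpoint out of range")
            if (self.bond_list[:, 0] == self.bond_list[:, 1]).any():
                raise ValueError("self-loop bond")
            keys = {tuple(sorted(e)) for e in self.bond_list.tolist()}
            if len(keys) != self.num_bonds:
                raise ValueError("duplicate undirected bond")


@dataclass
class LabeledDataset:
    """Graphs plus a molecules x tasks label matrix.

    Classification labels live in {0, 1, NaN} with NaN marking missing
    entries (multi-task panels such as Tox21 are sparse); regression labels
    are real numbers.
    """

    graphs: list[MolecularGraph]
    labels: np.ndarray             # (n_molecules, n_tasks) float, NaN = missing
    task_kind: str                 # "classification" | "regression"
    smiles: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.labels) != len(self.graphs):
            raise ValueError("label row count must equal graph count")
        if self.task_kind not in ("classification", "regression"):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        if self.task_kind == "classification":
            vals = self.labels[~np.isnan(self.labels)]
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("classification labels must be 0/1/missing")

    def __len__(self) -> int:
        return len(self.graphs)

    @property
    def num_tasks(self) -> int:
        return self.labels.shape[1]


def mol_to_graph(mol: Chem.Mol, smiles: str = "") -> MolecularGraph:
    """Featurize an RDKit molecule (hydrogens implicit)."""
    n = mol.GetNumAtoms()
    atom_feats = np.zeros((n, 2), dtype=np.int64)
    for atom in mol.GetAtoms():
        atom_feats[atom.GetIdx(), 0] = atom.GetAtomicNum() - 1
        atom_feats[atom.GetIdx(), 1] = _CHIRALITY_MAP.get(atom.GetChiralTag(), 0)
    bonds = []
    bond_feats = []
    for bond in mol.GetBonds():
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        bond_feats.append(
            (_BOND_TYPE_MAP[bond.GetBondType()], _BOND_DIR_MAP.get(bond.GetBondDir(), 0))
        )
    g = MolecularGraph(
        num_atoms=n,
        atom_features=atom_feats,
        bond_list=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_features=np.asarray(bond_feats, dtype=np.int64).reshape(-1, 2),
        smiles=smiles,
    )
    g.validate()
    return g


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a featurized :class:`MolecularGraph`.

    Raises :class:`SmilesParseError` for strings RDKit rejects, so callers
    batch-loading a library can skip and count bad rows.
    """
    if not smiles:
        raise SmilesParseError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(smiles)
    return mol_to_graph(mol, smiles=smiles)


def read_dataset(
    path: str | Path,
    task_columns: list[str],
    task_kind: str,
) -> LabeledDataset:
    """Load a labeled CSV (``smiles`` column + task columns).

    Rows with unparseable SMILES are dropped with a logged count; empty label
    cells are preserved as NaN and later excluded from losses and metrics.
    SDF files are accepted via the same parse path (labels from SD properties).
    """
    path = Path(path)
    if path.suffix.lower() == ".sdf":
        df = _read_sdf(path, task_columns)
    else:
        df = pd.read_csv(path)
    if "smiles" not in df.columns:
        raise KeyError(f"{path} has no 'smiles' column")
    missing_cols = [c for c in task_columns if c not in df.columns]
    if missing_cols:
        raise KeyError(f"{path} missing task columns {missing_cols}")

    graphs: list[MolecularGraph] = []
    rows: list[np.ndarray] = []
    smiles_kept: list[str] = []
    n_bad = 0
    for _, row in df.iterrows():
        try:
            g = parse_smiles(str(row["smiles"]))
        except SmilesParseError:
            n_bad += 1
            continue
        graphs.append(g)
        smiles_kept.append(str(row["smiles"]))
        rows.append(pd.to_numeric(row[task_columns], errors="coerce").to_numpy(dtype=np.float64))
    if n_bad:
        logger.warning("dropped %d unparseable SMILES rows from %s", n_bad, path)
    labels = np.vstack(rows) if rows else np.zeros((0, len(task_columns)))
    return LabeledDataset(graphs=graphs, labels=labels, task_kind=task_kind, smiles=smiles_kept)


def _read_sdf(path: Path, task_columns: list[str]) -> pd.DataFrame:
    records = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            records.append({"smiles": ""})
            continue
        rec = {"smiles": Chem.MolToSmiles(mol)}
        for c in task_columns:
            rec[c] = mol.GetProp(c) if mol.HasProp(c) else np.nan
        records.append(rec)
    return pd.DataFrame.from_records(records)


def read_smiles_library(path: str | Path) -> tuple[list[MolecularGraph], int]:
    """Load an unlabeled SMILES library (CSV with a ``smiles`` column).

    Returns the parsed graphs and the number of dropped rows.
    """
    df = pd.read_csv(path)
    if "smiles" not in df.columns:
        raise KeyError(f"{path} has no 'smiles' column")
    graphs = []
    n_bad = 0
    for s in df["smiles"].astype(str):
        try:
            graphs.append(parse_smiles(s))
        except SmilesParseError:
            n_bad += 1
    if n_bad:
        logger.warning("dropped %d unparseable SMILES rows from %s", n_bad, path)
    return graphs, n_bad
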