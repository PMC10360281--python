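"""BRICS-based atom partitioning.

The contrastive channel needs every atom assigned to exactly one fragment of
the *original* graph, so instead of enumerating BRICS fragments (which emit
dummy attachment atoms and may overlap), we identify the BRICS-cleavable
bonds, delete them, and take connected components as fragments.  Fragments
are indexed by their smallest contained atom index, which makes the fragment
ordering deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

from .mol_io import MolecularGraph, SmilesParseError

__all__ = ["FragmentAssignment", "brics_cut_bonds", "brics_partition"]


@dataclass
class FragmentAssignment:
    """Surjective map atom -> fragment index; fragments partition the atoms."""

    fragment_of_atom: np.ndarray   # (num_atoms,) int in [0, num_fragments)
    num_fragments: int

    def atoms_of(self, m: int) -> np.ndarray:
        return np.flatnonzero(self.fragment_of_atom == m)

    def fragment_sizes(self) -> np.ndarray:
        return np.bincount(self.fragment_of_atom, minlength=self.num_fragments)

    def validate(self, num_atoms: int) -> None:
        if len(self.fragment_of_atom) != num_atoms:
            raise ValueError("assignment length mismatch")
        if self.num_fragments < 1:
            raise ValueError("need at least one fragment")
        present = np.unique(self.fragment_of_atom)
        if not np.array_equal(present, np.arange(self.num_fragments)):
            raise ValueError("fragment indices must be 0..num_fragments-1")


def brics_cut_bonds(graph: MolecularGraph) -> set[tuple[int, int]]:
    """Return the BRICS-cleavable bonds as sorted atom-index pairs."""
    mol = Chem.MolFromSmiles(graph.smiles) if graph.smiles else None
    if mol is None:
        raise SmilesParseError(graph.smiles)
    return {tuple(sorted(b[0])) for b in BRICS.FindBRICSBonds(mol)}


def brics_partition(graph: MolecularGraph) -> FragmentAssignment:
    """Partition a molecule's atoms into BRICS fragments.

    Cleavable bonds are removed and the connected components of what remains
    become the fragments; no dummy atoms are introduced.  A molecule with no
    cleavable bond is a single fragment (per connected component for
    multi-component SMILES).
    """
    cuts = brics_cut_bonds(graph)
    n = graph.num_atoms
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for u, v in graph.bond_list:
        if tuple(sorted((int(u), int(v)))) in cuts:
            continue
        ru, rv = find(int(u)), find(int(v))
        if ru != rv:
            parent[max(ru, rv)] = min(ru, rv)

    roots = np.array([find(i) for i in range(n)])
    # order fragments by smallest contained atom index (== root, since
    # union always keeps the smaller root)
    order = {r: k for k, r in enumerate(sorted(set(roots.tolist())))}
    frag = np.array([order[r] for r in roots], dtype=np.int64)
    fa = FragmentAssignment(fragment_of_atom=frag, num_fragments=len(order))
    fa.validate(n)
    return fa
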