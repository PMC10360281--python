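"""Deterministic toy molecule libraries for tests and desk-scale runs.

Molecules are assembled combinatorially as core + linker + tail, with the
linkers (amide, ester, aryl/alkyl ether) drawn from bond environments the
BRICS rules cleave, so nearly every emitted molecule decomposes into at
least two fragments.  With ``family_labels`` the library carries two
structural families — aromatic-core vs aliphatic-core — whose cores have
*identical heavy-atom composition* (benzene vs cyclohexane, naphthalene vs
decalin); separating them requires bond/connectivity information rather than
atom counts.  A continuous companion label correlates with the BRICS
fragment count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .fragmentation import brics_partition
from .mol_io import parse_smiles

__all__ = ["ToyLibrarySpec", "generate_library", "write_library"]

AROMATIC_CORES = ["c1ccc({g})cc1", "c1ccc2cc({g})ccc2c1"]
ALIPHATIC_CORES = ["C1CCC({g})CC1", "C1CCC2CC({g})CCC2C1"]
LINKERS = ["C(=O)N", "C(=O)O", "O"]
# chain tails plus ring-terminated tails (ring digit 3 avoids clashing with
# core ring closures); ring tails diversify Murcko scaffolds so scaffold
# splits have many groups to distribute
BASE_TAILS = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC",
    "C(C)C", "CC(C)C", "C(C)CC", "CC(C)CC",
    "CCO", "CCCO", "CCN", "CCCN", "CCOC", "CC(C)CCC",
    "C3CC3", "CC3CC3", "CCC3CC3", "C3CCC3",
    "CC3CCC3", "CCC3CCC3", "C3CCCC3", "CC3CCCC3",
]


@dataclass
class ToyLibrarySpec:
    n_molecules: int
    seed: int = 0
    family_labels: bool = False

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


def _tails(min_count: int) -> list[str]:
    tails = list(BASE_TAILS)
    k = 7
    while len(tails) < min_count:
        tails.append("C" * k)
        k += 1
    return tails


def _enumerate_family(cores: list[str], tails: list[str]) -> list[str]:
    out = []
    seen = set()
    for core in cores:
        for linker in LINKERS:
            for tail in tails:
                smi = core.format(g=linker + tail)
                canon = Chem.CanonSmiles(smi)
                if canon not in seen:
                    seen.add(canon)
                    out.append(smi)
    return out


def generate_library(spec: ToyLibrarySpec) -> pd.DataFrame:
    """Build the library as a DataFrame with a ``smiles`` column.

    With ``family_labels`` two extra columns are added: ``family`` (binary,
    1 = aromatic core) and ``frag_score`` (continuous, fragment-count
    driven).  Families are emitted in balanced counts (within one molecule)
    and the output is deterministic under the seed.
    """
    n = spec.n_molecules
    per_family = (n + 1) // 2
    tails_needed = -(-per_family // (len(AROMATIC_CORES) * len(LINKERS)))
    tails = _tails(tails_needed)
    rng = np.random.default_rng(spec.seed)

    arom = _enumerate_family(AROMATIC_CORES, tails)
    alip = _enumerate_family(ALIPHATIC_CORES, tails)
    arom = [arom[i] for i in rng.permutation(len(arom))][: (n + 1) // 2]
    alip = [alip[i] for i in rng.permutation(len(alip))][: n // 2]

    records = [(s, 1) for s in arom] + [(s, 0) for s in alip]
    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    rows = []
    for smi, fam in records:
        g = parse_smiles(smi)          # every emitted molecule must parse
        row = {"smiles": smi}
        if spec.family_labels:
            fa = brics_partition(g)
            row["family"] = fam
            row["frag_score"] = round(fa.num_fragments + 0.1 * g.num_atoms, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def write_library(spec: ToyLibrarySpec, path: str | Path) -> pd.DataFrame:
    df = generate_library(spec)
    df.to_csv(path, index=False)
    return df
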