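"""Decompose molecules into BRICS fragments as atom partitions.

The fragmenter finds the BRICS-cleavable bonds of each molecule, removes
them and reports the connected components as fragments on the original
atom numbering — no dummy atoms are introduced.
"""

from fragssl import brics_cut_bonds, brics_partition, parse_smiles

MOLECULES = [
    "CC",                      # ethane: nothing to cleave
    "CCOC(=O)c1ccccc1",        # ethyl benzoate: ester bonds cleave
    "CC(=O)Nc1ccc(O)cc1",      # paracetamol
]

for smiles in MOLECULES:
    graph = parse_smiles(smiles)
    cuts = brics_cut_bonds(graph)
    fa = brics_partition(graph)
    print(f"{smiles}")
    print(f"  atoms: {graph.num_atoms}, cut bonds: {sorted(cuts)}")
    print(f"  fragments ({fa.num_fragments}):", end=" ")
    print(", ".join(str(fa.atoms_of(m).tolist()) for m in range(fa.num_fragments)))

# Each fragment is a connected piece of the molecule; together the pieces
# cover every atom exactly once.  Molecules with no cleavable bond are a
# single fragment.
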