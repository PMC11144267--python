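"""Generate the per-residue atomic hydrophobicity constant table.

Atomic logP contributions follow the Wildman--Crippen atom typing as
implemented in rdkit.  For each of the 20 standard amino acids X a
Gly-X-Gly tripeptide is built, hydrogens are added, per-atom Crippen
contributions are computed, and every hydrogen's contribution is folded
onto its bonded heavy atom (united-atom constants, suitable for typing
deposited structures that carry no hydrogens).  The central residue of
the tripeptide provides the (residue, atom name) -> constant entries, so
backbone atoms are typed in a peptide-bonded context.  Terminal-specific
atoms (OXT) are harvested from the C-terminal glycine.

Usage:  python scripts/make_hydrophobicity_table.py
Writes: src/dmportrait/data/wildman_crippen_residue_logp.json
"""

import json
from pathlib import Path

import rdkit
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


def folded_contribs(mol_h):
    """Per-heavy-atom Crippen logP contributions with H folded in."""
    contribs = rdMolDescriptors._CalcCrippenContribs(mol_h)
    out = {}
    for atom in mol_h.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        total = contribs[atom.GetIdx()][0]
        for nb in atom.GetNeighbors():
            if nb.GetAtomicNum() == 1:
                total += contribs[nb.GetIdx()][0]
        out[atom.GetIdx()] = total
    return out


def residue_entries(mol_h, resno):
    vals = folded_contribs(mol_h)
    entries = {}
    for atom in mol_h.GetAtoms():
        info = atom.GetPDBResidueInfo()
        if info is None or atom.GetAtomicNum() == 1:
            continue
        if info.GetResidueNumber() != resno:
            continue
        entries[info.GetName().strip()] = round(vals[atom.GetIdx()], 4)
    return entries


def main():
    table = {}
    for aa in AA1:
        mol = Chem.MolFromSequence("G" + aa + "G")
        mol_h = Chem.AddHs(mol)
        table[AA3[aa]] = residue_entries(mol_h, 2)

    # terminal carboxylate oxygen from the C-terminal glycine
    mol_h = Chem.AddHs(Chem.MolFromSequence("GGG"))
    cterm = residue_entries(mol_h, 3)

    consistency = round(Crippen.MolLogP(mol_h, includeHs=True), 4)

    out = {
        "meta": {
            "scheme": "wildman-crippen-1999",
            "generator": "rdkit " + rdkit.__version__,
            "units": "octanol-water logP contribution per heavy atom, "
                     "implicit-hydrogen folded",
            "context": "central residue of Gly-X-Gly tripeptide",
            "mol_logp_GGG_with_H": consistency,
        },
        "residues": table,
        "terminal": {"OXT": cterm["OXT"]},
    }
    dest = Path(__file__).resolve().parents[1] / "src" / "dmportrait" / \
        "data" / "wildman_crippen_residue_logp.json"
    dest.write_text(json.dumps(out, indent=1, sort_keys=True) + "\n")
    print(f"wrote {dest}")


if __name__ == "__main__":
    main()
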