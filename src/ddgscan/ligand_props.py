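"""Small-molecule descriptors for the bound inhibitors.

A ligand enters as an SDF/MOL V2000 block (or SMILES through the adapter)
and leaves as a compact descriptor record: topological polar surface area
(Ertl fragment contributions), rotatable bonds, ring count, positively
ionizable centres, H-bond donors/acceptors and heavy-atom count. RDKit
supplies the chemistry; this module fixes the descriptor semantics and the
stable column names used by feature assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import Descriptors, Lipinski, rdMolDescriptors

SUPPORTED_ELEMENTS = frozenset(
    {"C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H"}
)


class MolParseError(ValueError):
    """Raised when an SDF/MOL or SMILES input cannot be parsed."""


@dataclass(eq=False)
class MolecularGraph:
    """Light graph view over a parsed molecule (heavy atoms + bonds)."""

    mol: Chem.Mol
    atoms: list[dict]
    bonds: list[dict]


def _wrap(mol: Chem.Mol) -> MolecularGraph:
    atoms = [
        {
            "element": a.GetSymbol(),
            "formal_charge": a.GetFormalCharge(),
            "aromatic": a.GetIsAromatic(),
            "n_h": a.GetTotalNumHs(),
        }
        for a in mol.GetAtoms()
    ]
    bonds = [
        {
            "begin": b.GetBeginAtomIdx(),
            "end": b.GetEndAtomIdx(),
            "order": ("aromatic" if b.GetIsAromatic()
                      else int(b.GetBondTypeAsDouble())),
            "in_ring": b.IsInRing(),
        }
        for b in mol.GetBonds()
    ]
    return MolecularGraph(mol=mol, atoms=atoms, bonds=bonds)


def read_mol(text: str) -> MolecularGraph:
    """Parse an SDF/MOL V2000 block."""
    mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
    if mol is None:
        raise MolParseError("could not parse MOL/SDF block")
    return _wrap(mol)


def read_smiles(smiles: str) -> MolecularGraph:
    """SMILES adapter (same downstream semantics as read_mol)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MolParseError(f"could not parse SMILES {smiles!r}")
    return _wrap(mol)


@dataclass(frozen=True)
class LigandDescriptors:
    tpsa: float
    rotatable_bonds: int
    ring_count: int
    pos_ionizable: int
    hbd: int
    hba: int
    heavy_atoms: int
    logp: float | None = None

    def as_features(self) -> dict[str, float]:
        out = {
            "lig:tpsa": self.tpsa,
            "lig:rotatable_bonds": float(self.rotatable_bonds),
            "lig:ring_count": float(self.ring_count),
            "lig:pos_ionizable": float(self.pos_ionizable),
            "lig:hbd": float(self.hbd),
            "lig:hba": float(self.hba),
            "lig:heavy_atoms": float(self.heavy_atoms),
        }
        if self.logp is not None:
            out["lig:logp"] = self.logp
        return out


def _count_pos_ionizable(mol: Chem.Mol) -> int:
    """Basic amines plus amidine/guanidine groups, each group counted once."""
    count = 0
    group_nitrogens: set[int] = set()
    for atom in mol.GetAtoms():
        # amidine/guanidine carbon: C doubly bonded to one N, singly to >=1 N
        if atom.GetSymbol() == "C" and not atom.GetIsAromatic():
            double_n = single_n = 0
            members = []
            for b in atom.GetBonds():
                other = b.GetOtherAtom(atom)
                if other.GetSymbol() != "N" or other.GetIsAromatic():
                    continue
                if b.GetBondTypeAsDouble() == 2.0:
                    double_n += 1
                elif b.GetBondTypeAsDouble() == 1.0:
                    single_n += 1
                members.append(other.GetIdx())
            if double_n == 1 and single_n >= 1:
                count += 1
                group_nitrogens.update(members)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "N" or atom.GetIsAromatic():
            continue
        if atom.GetIdx() in group_nitrogens:
            continue
        if any(b.GetBondTypeAsDouble() != 1.0 for b in atom.GetBonds()):
            continue  # not sp3
        # amide / sulfonamide neighbours quench basicity
        quenched = False
        for b in atom.GetBonds():
            nb = b.GetOtherAtom(atom)
            if nb.GetSymbol() in ("C", "S"):
                for b2 in nb.GetBonds():
                    far = b2.GetOtherAtom(nb)
                    if far.GetIdx() == atom.GetIdx():
                        continue
                    if b2.GetBondTypeAsDouble() >= 2.0 and far.GetSymbol() in (
                        "O", "S", "N",
                    ):
                        quenched = True
            elif nb.GetSymbol() not in ("C", "H"):
                quenched = True  # N-O, N-N etc.
        if not quenched:
            count += 1
    return count


def compute_descriptors(
    g: MolecularGraph, include_s_p_tpsa: bool = True, with_logp: bool = False
) -> LigandDescriptors:
    """Descriptor record for one ligand.

    TPSA uses Ertl fragment contributions; ``include_s_p_tpsa`` switches on
    the S/P extension (default on, matching common toolkit behaviour).
    """
    mol = g.mol
    bad = sorted(
        {a.GetSymbol() for a in mol.GetAtoms()} - SUPPORTED_ELEMENTS
    )
    if bad:
        raise ValueError(f"unsupported element(s): {', '.join(bad)}")
    return LigandDescriptors(
        tpsa=float(Descriptors.TPSA(mol, includeSandP=include_s_p_tpsa)),
        rotatable_bonds=int(Lipinski.NumRotatableBonds(mol)),
        ring_count=int(rdMolDescriptors.CalcNumRings(mol)),
        pos_ionizable=_count_pos_ionizable(mol),
        hbd=int(Lipinski.NumHDonors(mol)),
        hba=int(Lipinski.NumHAcceptors(mol)),
        heavy_atoms=int(mol.GetNumHeavyAtoms()),
        logp=float(Descriptors.MolLogP(mol)) if with_logp else None,
    )
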