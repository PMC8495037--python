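"""Pharmacophore atom typing.

Seven coarse chemical roles — Hydrophobic, Positive, Negative, HAcceptor,
HDonor, Aromatic, Neutral — are assigned to every heavy atom from a shipped
rule table (data/pharmacophore_rules.csv). An atom may carry several labels
(e.g. Lys NZ is both Positive and HDonor); an atom with no specific role is
Neutral. The fixed class order below defines vector layouts everywhere in
the package.
"""

from __future__ import annotations

import csv
import logging
from functools import lru_cache
from importlib import resources

import numpy as np

from .constants import AA_1TO3, BACKBONE_ATOMS, SIDE_CHAIN_ATOMS
from .structure_io import Atom, Structure

logger = logging.getLogger(__name__)

CLASSES: tuple[str, ...] = (
    "Hydrophobic",
    "Positive",
    "Negative",
    "HAcceptor",
    "HDonor",
    "Aromatic",
    "Neutral",
)
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

RULES_VERSION = "ddgscan-rules-v1"

# Element fallback for het-group atoms (ligands, ions), where the PDB record
# carries no bond information. Documented reconstruction: N is treated as an
# ambivalent donor/acceptor, O as acceptor, apolar elements as hydrophobic.
_HET_ELEMENT_CLASSES: dict[str, frozenset[str]] = {
    "C": frozenset({"Hydrophobic"}),
    "N": frozenset({"HDonor", "HAcceptor"}),
    "O": frozenset({"HAcceptor"}),
    "S": frozenset({"Hydrophobic"}),
    "F": frozenset({"Hydrophobic"}),
    "CL": frozenset({"Hydrophobic"}),
    "BR": frozenset({"Hydrophobic"}),
    "I": frozenset({"Hydrophobic"}),
    "MG": frozenset({"Positive"}),
    "ZN": frozenset({"Positive"}),
    "MN": frozenset({"Positive"}),
    "FE": frozenset({"Positive"}),
    "NA": frozenset({"Positive"}),
    "K": frozenset({"Positive"}),
    "CA": frozenset({"Positive"}),
}

AtomLabeling = dict  # id(atom) is the key; values are frozensets of classes


@lru_cache(maxsize=1)
def load_rules() -> dict[tuple[str, str], frozenset[str]]:
    """Parse the shipped rule table into a (residue, atom) -> classes map."""
    rules: dict[tuple[str, str], frozenset[str]] = {}
    path = resources.files("ddgscan").joinpath("data/pharmacophore_rules.csv")
    with path.open() as fh:
        reader = csv.reader(
            line for line in fh if line.strip() and not line.startswith("#")
        )
        header = next(reader)
        assert header == ["residue", "atom", "classes"]
        for res, atom, classes in reader:
            cset = frozenset(classes.split("|"))
            unknown = cset - set(CLASSES)
            if unknown:
                raise ValueError(f"unknown classes {unknown} in rule table")
            rules[(res, atom)] = cset
    return rules


def classes_for(residue_name: str, atom_name: str) -> frozenset[str]:
    """Rule-table lookup; Neutral fallback with a logged warning."""
    rules = load_rules()
    hit = rules.get((residue_name, atom_name)) or rules.get(("*", atom_name))
    if hit is None:
        logger.warning(
            "no pharmacophore rule for %s/%s; labeling Neutral",
            residue_name, atom_name,
        )
        return frozenset({"Neutral"})
    return hit


def label_protein_atoms(s: Structure) -> AtomLabeling:
    """Label every non-het heavy atom; totality is guaranteed."""
    labeling: AtomLabeling = {}
    for atom in s.atoms:
        if atom.is_het:
            continue
        labeling[id(atom)] = classes_for(atom.residue.name, atom.name)
    return labeling


def label_het_atoms(atoms: list[Atom]) -> AtomLabeling:
    """Element-based labels for het (ligand/ion) atoms."""
    labeling: AtomLabeling = {}
    for atom in atoms:
        labeling[id(atom)] = _HET_ELEMENT_CLASSES.get(
            atom.element, frozenset({"Neutral"})
        )
    return labeling


def label_structure(s: Structure) -> AtomLabeling:
    """Full labeling: table rules for protein atoms, element rules for het."""
    labeling = label_protein_atoms(s)
    labeling.update(label_het_atoms([a for a in s.atoms if a.is_het]))
    return labeling


@lru_cache(maxsize=32)
def residue_class_counts(aa: str) -> np.ndarray:
    """Per-class atom counts of one amino acid's idealized heavy-atom topology.

    An atom carrying k labels contributes to k cells.
    """
    if aa not in AA_1TO3:
        raise ValueError(f"non-canonical amino acid code {aa!r}")
    name3 = AA_1TO3[aa]
    counts = np.zeros(len(CLASSES), dtype=int)
    for atom_name in BACKBONE_ATOMS + SIDE_CHAIN_ATOMS[name3]:
        for cls in classes_for(name3, atom_name):
            counts[CLASS_INDEX[cls]] += 1
    counts.setflags(write=False)
    return counts


def delta_pharmacophore(wt: str, mt: str) -> np.ndarray:
    """Signed change in per-class atom counts for a wt -> mt substitution."""
    return residue_class_counts(mt).astype(int) - residue_class_counts(wt)


def delta_feature_names() -> list[str]:
    return [f"dpharm:{c}" for c in CLASSES]
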