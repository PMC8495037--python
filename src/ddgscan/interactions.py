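"""Typed interatomic contact detection and wild-type/mutant contact deltas.

Contacts between a residue environment and a partner (ligand or the rest of
the protein) are classified into seven types with distance-only geometric
criteria — the inputs are X-ray heavy-atom models without hydrogens, so
angle terms that require explicit H are replaced by distance cutoffs. The
criteria live in an editable table (``DEFAULT_CRITERIA``).

Mutant environments are approximated by truncating the mutated side chain to
the atoms shared between wild-type and mutant topologies (worst case Cβ);
no rotamer building is attempted. A user-supplied mutant structure can be
used instead wherever a ``Structure`` is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .constants import (
    AA_1TO3,
    AROMATIC_RINGS,
    BACKBONE_ATOMS,
    SIDE_CHAIN_ATOMS,
    VDW_RADII,
)
from .pharmacophore import AtomLabeling
from .structure_io import Atom, Residue, Structure

logger = logging.getLogger(__name__)

CONTACT_TYPES: tuple[str, ...] = (
    "hydrogen_bond",
    "vdw_clash",
    "carbon_pi",
    "amide_ring",
    "ring_ring",
    "ionic",
    "hydrophobic_contact",
)

# Distance criteria (Angstrom); vdw_clash_tolerance is subtracted from the
# sum of Bondi radii. Editable: pass a modified copy to find_contacts.
DEFAULT_CRITERIA: dict[str, float] = {
    "hydrogen_bond": 3.5,
    "vdw_clash_tolerance": 0.1,
    "ionic": 4.0,
    "hydrophobic_contact": 4.5,
    "carbon_pi": 4.5,
    "amide_ring": 4.5,
    "ring_ring": 5.5,
}

_COVALENT_BOND_MAX = 1.75  # het-group ring perception bond cutoff
_WARNED_GROWING: set[tuple[str, str]] = set()


@dataclass(frozen=True)
class Contact:
    type: str
    members: tuple
    distance: float


@dataclass
class ContactSummary:
    """Per-type contact counts, keyed by scope ('ligand' / 'protein')."""

    counts: dict[str, dict[str, int]]

    @classmethod
    def from_contacts(cls, by_scope: dict[str, list[Contact]]) -> "ContactSummary":
        counts = {
            scope: {t: 0 for t in CONTACT_TYPES} for scope in by_scope
        }
        for scope, contacts in by_scope.items():
            for c in contacts:
                counts[scope][c.type] += 1
        return cls(counts=counts)


def _protein_rings(atoms: list[Atom]) -> list[tuple[tuple, np.ndarray]]:
    """Aromatic rings from residue templates; only complete rings count."""
    by_res: dict[int, list[Atom]] = {}
    residues: dict[int, Residue] = {}
    for a in atoms:
        if a.is_het:
            continue
        by_res.setdefault(id(a.residue), []).append(a)
        residues[id(a.residue)] = a.residue
    rings = []
    for rid, res_atoms in by_res.items():
        res = residues[rid]
        for ring_names in AROMATIC_RINGS.get(res.name, ()):
            members = {n: None for n in ring_names}
            for a in res_atoms:
                if a.name in members:
                    members[a.name] = a
            if all(v is not None for v in members.values()):
                ring = tuple(members.values())
                centroid = np.mean([a.coords for a in ring], axis=0)
                rings.append((ring, centroid))
    return rings


def _het_rings(atoms: list[Atom]) -> list[tuple[tuple, np.ndarray]]:
    """Geometric 5/6-membered C/N rings in het groups (no bond records)."""
    het = [a for a in atoms if a.is_het and a.element in ("C", "N")]
    if len(het) < 5:
        return []
    g = nx.Graph()
    g.add_nodes_from(range(len(het)))
    xyz = np.array([a.coords for a in het])
    d = np.sqrt(((xyz[:, None] - xyz[None]) ** 2).sum(-1))
    for i in range(len(het)):
        for j in range(i + 1, len(het)):
            if d[i, j] <= _COVALENT_BOND_MAX:
                g.add_edge(i, j)
    rings = []
    for cycle in nx.minimum_cycle_basis(g):
        if len(cycle) in (5, 6):
            ring = tuple(het[i] for i in cycle)
            rings.append((ring, np.mean([a.coords for a in ring], axis=0)))
    return rings


def ring_centroids(
    atoms_or_structure, labeling: AtomLabeling | None = None
) -> list[tuple[tuple, np.ndarray]]:
    """(ring atoms, centroid) for every aromatic ring system of 5-6 atoms.

    Protein rings come from residue templates (Trp yields two); het-group
    rings from geometric cycle perception on C/N atoms.
    """
    atoms = (
        atoms_or_structure.atoms
        if isinstance(atoms_or_structure, Structure)
        else list(atoms_or_structure)
    )
    return _protein_rings(atoms) + _het_rings(atoms)


def _amide_centroids(atoms: list[Atom]) -> list[tuple[tuple, np.ndarray]]:
    """Backbone amide-group (N, C, O) centroids per residue present."""
    by_res: dict[int, dict[str, Atom]] = {}
    for a in atoms:
        if not a.is_het and a.name in ("N", "C", "O"):
            by_res.setdefault(id(a.residue), {})[a.name] = a
    out = []
    for grp in by_res.values():
        if set(grp) == {"N", "C", "O"}:
            members = (grp["N"], grp["C"], grp["O"])
            out.append((members, np.mean([a.coords for a in members], axis=0)))
    return out


def find_contacts(
    site_atoms: list[Atom],
    partner_atoms: list[Atom],
    labeling: AtomLabeling,
    criteria: dict[str, float] | None = None,
) -> list[Contact]:
    """Detect typed contacts between two labeled heavy-atom sets."""
    if criteria is None:
        criteria = DEFAULT_CRITERIA
    missing = set(DEFAULT_CRITERIA) - set(criteria)
    if missing:
        raise ValueError(f"criteria missing entries: {sorted(missing)}")
    contacts: list[Contact] = []
    if not site_atoms or not partner_atoms:
        return contacts

    a_xyz = np.array([a.coords for a in site_atoms])
    b_xyz = np.array([b.coords for b in partner_atoms])
    dmat = np.sqrt(((a_xyz[:, None] - b_xyz[None]) ** 2).sum(-1))
    lab = lambda a: labeling[id(a)]

    for i, a in enumerate(site_atoms):
        la = lab(a)
        for j, b in enumerate(partner_atoms):
            d = float(dmat[i, j])
            lb = lab(b)
            if d <= criteria["hydrogen_bond"] and (
                ("HDonor" in la and "HAcceptor" in lb)
                or ("HAcceptor" in la and "HDonor" in lb)
            ):
                contacts.append(Contact("hydrogen_bond", (a, b), d))
            r_sum = VDW_RADII.get(a.element, 1.7) + VDW_RADII.get(b.element, 1.7)
            if 0 < d < r_sum - criteria["vdw_clash_tolerance"]:
                contacts.append(Contact("vdw_clash", (a, b), d))
            if d <= criteria["ionic"] and (
                ("Positive" in la and "Negative" in lb)
                or ("Negative" in la and "Positive" in lb)
            ):
                contacts.append(Contact("ionic", (a, b), d))
            if (
                d <= criteria["hydrophobic_contact"]
                and a.element == "C" == b.element
                and "Hydrophobic" in la
                and "Hydrophobic" in lb
            ):
                contacts.append(Contact("hydrophobic_contact", (a, b), d))

    site_rings = ring_centroids(site_atoms)
    partner_rings = ring_centroids(partner_atoms)

    # carbon_pi: carbon on one side vs aromatic ring centroid on the other
    for atoms, rings in ((site_atoms, partner_rings), (partner_atoms, site_rings)):
        for a in atoms:
            if a.element != "C":
                continue
            for ring, centroid in rings:
                d = float(np.linalg.norm(a.coords - centroid))
                if d <= criteria["carbon_pi"]:
                    contacts.append(Contact("carbon_pi", (a, ring), d))

    # amide_ring: backbone amide centroid vs ring centroid across the sets
    for amides, rings in (
        (_amide_centroids(site_atoms), partner_rings),
        (_amide_centroids(partner_atoms), site_rings),
    ):
        for members, ac in amides:
            for ring, rc in rings:
                d = float(np.linalg.norm(ac - rc))
                if d <= criteria["amide_ring"]:
                    contacts.append(Contact("amide_ring", (members, ring), d))

    for ring_a, ca in site_rings:
        for ring_b, cb in partner_rings:
            d = float(np.linalg.norm(ca - cb))
            if d <= criteria["ring_ring"]:
                contacts.append(Contact("ring_ring", (ring_a, ring_b), d))

    return contacts


def contact_summary(
    s: Structure,
    chain: str,
    seqnum: int,
    ligand_atoms: list[Atom],
    labeling: AtomLabeling,
    radius: float = 10.0,
    icode: str = "",
    criteria: dict[str, float] | None = None,
) -> ContactSummary:
    """Site-residue contacts split into ligand and protein scopes.

    The site residue's atoms are tested against the ligand and against the
    surrounding protein atoms within ``radius``.
    """
    from .structure_io import get_environment

    site = s.get_residue(chain, seqnum, icode).atoms
    env = [
        a
        for a in get_environment(s, chain, seqnum, radius, icode=icode,
                                 include_het=False)
    ]
    return ContactSummary.from_contacts({
        "ligand": find_contacts(site, ligand_atoms, labeling, criteria),
        "protein": find_contacts(site, env, labeling, criteria),
    })


def delta_contacts(wt: ContactSummary, mt: ContactSummary) -> dict[str, dict[str, int]]:
    """Wild-type minus mutant contact counts, per scope and type."""
    if set(wt.counts) != set(mt.counts):
        raise ValueError(
            f"scope mismatch: {sorted(wt.counts)} vs {sorted(mt.counts)}"
        )
    return {
        scope: {
            t: wt.counts[scope][t] - mt.counts[scope][t] for t in CONTACT_TYPES
        }
        for scope in wt.counts
    }


def mutant_environment(
    s: Structure, chain: str, seqnum: int, mt: str, icode: str = ""
) -> Structure:
    """Approximate mutant structure by common-atom side-chain truncation.

    The site residue keeps its backbone plus the side-chain atoms shared by
    the wild-type and mutant topologies (by atom name), and is renamed to the
    mutant residue. No atoms are ever built, so mutations to a larger residue
    (e.g. Gly->Ala) keep the wild-type atom set with a logged warning.
    """
    if mt not in AA_1TO3:
        raise ValueError(f"non-canonical mutant amino acid {mt!r}")
    mt3 = AA_1TO3[mt]
    out = s.copy()
    res = out.get_residue(chain, seqnum, icode)
    keep = set(BACKBONE_ATOMS) | (
        set(SIDE_CHAIN_ATOMS.get(res.name, ())) & set(SIDE_CHAIN_ATOMS[mt3])
    )
    wt_topology = set(SIDE_CHAIN_ATOMS.get(res.name, ()))
    mt_topology = set(SIDE_CHAIN_ATOMS[mt3])
    if not (wt_topology >= mt_topology):
        pair = (res.name, mt3)
        if pair not in _WARNED_GROWING:  # once per substitution type
            _WARNED_GROWING.add(pair)
            logger.warning(
                "mutation %s->%s enlarges the side chain: no atoms built, "
                "mutant keeps the truncated wild-type side chain",
                res.name, mt3,
            )
    res.atoms = [a for a in res.atoms if a.name in keep]
    res.name = mt3
    return out
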