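"""Protein-ligand structure handling.

Parses PDB text into a light heavy-atom model, extracts residue
microenvironments, and computes the geometric quantities downstream feature
engineering needs: minimum ligand distances and Shrake-Rupley solvent
accessibility.

Conventions (deliberate, see docs/methods.md):

* model 1 only; hydrogens and waters are dropped at parse time;
* altloc 'A' (or blank) wins; if a site has neither, the highest-occupancy
  conformer is kept — one deterministic conformer per atom site;
* residue numbering is PDB author numbering with insertion codes honored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    AA_3TO1,
    MAX_SASA_GLY_X_GLY,
    VDW_RADII,
    WATER_NAMES,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ComplexRecord",
    "PDBParseError",
    "ResidueNotFoundError",
    "read_pdb",
    "get_environment",
    "min_distance_to_ligand",
    "shrake_rupley_sasa",
    "write_pdb_fragment",
]


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class ResidueNotFoundError(KeyError):
    """Raised when a (chain, seqnum, icode) lookup fails."""


@dataclass(eq=False)
class Residue:
    chain: str
    seqnum: int
    icode: str
    name: str
    atoms: list["Atom"] = field(default_factory=list, repr=False)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seqnum, self.icode)

    @property
    def one_letter(self) -> str | None:
        return AA_3TO1.get(self.name)

    def atom(self, name: str) -> "Atom | None":
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass(eq=False)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float
    is_het: bool
    residue: Residue = field(repr=False, default=None)


@dataclass(eq=False)
class Structure:
    residues: list[Residue] = field(default_factory=list)
    _index: dict[tuple[str, int, str], Residue] = field(default_factory=dict, repr=False)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def add_residue(self, res: Residue) -> None:
        if res.key in self._index:
            raise ValueError(f"duplicate residue key {res.key}")
        self.residues.append(res)
        self._index[res.key] = res

    def get_residue(self, chain: str, seqnum: int, icode: str = "") -> Residue:
        try:
            return self._index[(chain, seqnum, icode)]
        except KeyError:
            raise ResidueNotFoundError(
                f"residue {chain}/{seqnum}{icode or ''} not found"
            ) from None

    def ligand_groups(self) -> dict[tuple[str, str], list[Atom]]:
        """Het groups keyed by (residue name, chain)."""
        groups: dict[tuple[str, str], list[Atom]] = {}
        for res in self.residues:
            het = [a for a in res.atoms if a.is_het]
            if het:
                groups.setdefault((res.name, res.chain), []).extend(het)
        return groups

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_het]

    def copy(self) -> "Structure":
        out = Structure()
        for res in self.residues:
            new_res = Residue(res.chain, res.seqnum, res.icode, res.name)
            for a in res.atoms:
                new_res.atoms.append(
                    Atom(a.serial, a.name, a.element, a.coords.copy(),
                         a.occupancy, a.is_het, new_res)
                )
            out.add_residue(new_res)
        return out


@dataclass(eq=False)
class ComplexRecord:
    """A protein-ligand complex: one structure plus the ligand atom subset."""

    structure: Structure
    ligand_id: str
    binding_mode: str  # type_I | type_II | endogenous
    ligand_atoms: list[Atom]

    def __post_init__(self) -> None:
        if self.binding_mode not in {"type_I", "type_II", "endogenous"}:
            raise ValueError(f"unknown binding mode {self.binding_mode!r}")
        if not all(a.is_het for a in self.ligand_atoms):
            raise ValueError("ligand_atoms must all be het-flagged")


def _validate_coordinate_records(text: str) -> None:
    """Cheap fixed-column sanity scan so errors carry a line number."""
    seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        seen = True
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: coordinate record too short")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: unparseable {what} coordinate "
                    f"{line[lo:hi]!r}"
                ) from None
    if not seen:
        raise PDBParseError("no ATOM or HETATM records in input")


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    for a in atoms:
        if a.altloc in ("", "\0", "A"):
            return a
    return max(atoms, key=lambda a: a.occ)


def read_pdb(text: str) -> Structure:
    """Parse PDB text (model 1, heavy atoms, waters excluded)."""
    if not text or not text.strip():
        raise PDBParseError("empty PDB input")
    _validate_coordinate_records(text)
    gst = gemmi.read_pdb_string(text)
    if len(gst) == 0:
        raise PDBParseError("no models in PDB input")
    model = gst[0]
    out = Structure()
    serial = 0
    for chain in model:
        for gres in chain:
            if gres.name in WATER_NAMES:
                continue
            is_het = gres.het_flag == "H"
            res = Residue(
                chain=chain.name,
                seqnum=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                name=gres.name,
            )
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                by_name.setdefault(ga.name, []).append(ga)
            for name, alts in by_name.items():
                ga = _pick_altloc(alts) if len(alts) > 1 else alts[0]
                serial += 1
                element = ga.element.name.upper()
                if not element:
                    raise PDBParseError(f"atom {name} has no element")
                atom = Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z], dtype=float),
                    occupancy=ga.occ,
                    is_het=is_het,
                    residue=res,
                )
                res.atoms.append(atom)
            if res.atoms:
                out.add_residue(res)
    if not out.residues:
        raise PDBParseError("no heavy atoms after filtering")
    return out


def get_environment(
    s: Structure,
    chain: str,
    seqnum: int,
    radius: float,
    icode: str = "",
    include_self: bool = False,
    include_het: bool = True,
) -> list[Atom]:
    """Heavy atoms within ``radius`` of any atom of the site residue.

    The site residue's own atoms are excluded unless ``include_self``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    site = s.get_residue(chain, seqnum, icode)
    site_xyz = np.array([a.coords for a in site.atoms])
    others = [
        a
        for a in s.atoms
        if a.residue is not site and (include_het or not a.is_het)
    ]
    out: list[Atom] = list(site.atoms) if include_self else []
    if others:
        xyz = np.array([a.coords for a in others])
        dmin = np.sqrt(
            ((xyz[:, None, :] - site_xyz[None, :, :]) ** 2).sum(-1)
        ).min(axis=1)
        out.extend(a for a, d in zip(others, dmin) if d <= radius)
    return out


def min_distance_to_ligand(
    s: Structure, chain: str, seqnum: int, ligand_atoms: list[Atom], icode: str = ""
) -> float:
    """Minimum heavy-atom distance from the site residue to the ligand."""
    if not ligand_atoms:
        raise ValueError("empty ligand atom set")
    site = s.get_residue(chain, seqnum, icode)
    a = np.array([at.coords for at in site.atoms])
    b = np.array([at.coords for at in ligand_atoms])
    return float(np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min())


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    s: Structure,
    probe: float = 1.4,
    n_points: int = 960,
) -> dict[tuple[str, int, str], dict[str, float]]:
    """Per-residue absolute and relative solvent-accessible surface area.

    Rolls a probe sphere over every heavy atom using a Fibonacci-lattice
    sampling of each expanded sphere; residue SASA is the sum over its atoms
    and relative accessibility divides by the Gly-X-Gly maximum for the
    residue type (None for non-standard residues).
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    atoms = s.atoms
    missing = sorted({a.element for a in atoms if a.element not in VDW_RADII})
    if missing:
        raise ValueError(f"no vdW radius for element(s): {', '.join(missing)}")
    xyz = np.array([a.coords for a in atoms])
    radii = np.array([VDW_RADII[a.element] for a in atoms])
    expanded = radii + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(xyz)
    max_reach = expanded.max()
    atom_sasa = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = xyz[i] + expanded[i] * sphere
        neighbors = [
            j for j in tree.query_ball_point(xyz[i], expanded[i] + max_reach)
            if j != i
        ]
        if neighbors:
            nxyz = xyz[neighbors]
            nrad = expanded[neighbors]
            d2 = ((pts[:, None, :] - nxyz[None, :, :]) ** 2).sum(-1)
            buried = (d2 < (nrad**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        atom_sasa[i] = frac * 4.0 * math.pi * expanded[i] ** 2
    idx = {id(a): i for i, a in enumerate(atoms)}
    out: dict[tuple[str, int, str], dict[str, float]] = {}
    for res in s.residues:
        total = float(sum(atom_sasa[idx[id(a)]] for a in res.atoms))
        max_ref = MAX_SASA_GLY_X_GLY.get(res.name)
        out[res.key] = {
            "sasa": total,
            "relative": (total / max_ref) if max_ref else None,
        }
    return out


def write_pdb_fragment(atoms: list[Atom]) -> str:
    """Format an atom subset as PDB text (debugging aid)."""
    lines = []
    for a in atoms:
        rec = "HETATM" if a.is_het else "ATOM  "
        r = a.residue
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{rec}{a.serial:>5d} {name}{'':1s}{r.name:>3s} {r.chain[:1]:1s}"
            f"{r.seqnum:>4d}{r.icode or ' ':1s}   "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
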