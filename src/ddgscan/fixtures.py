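"""Synthetic toy complexes and affinity datasets.

The generator builds a miniature protein-ligand world in which every stage
of the pipeline — parsing, labeling, signatures, contacts, learning,
saturation — runs end to end with no external downloads, and in which the
ground truth is known exactly: ΔΔG is a linear function of a named feature
subset plus Gaussian noise, so parameter-recovery tests have an analytic
target.

Geometry: backbone atoms on an ideal alpha-helix (rise 1.5 Å per residue,
100° twist, 2.3 Å radius) with one pseudo side-chain atom (Cβ) per residue;
ligands are short heteroatom chains placed 3-5 Å outside a designated pocket
residue. Nothing here is energetically realistic — it is a deterministic,
non-degenerate geometry for exercising the feature code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import AA_1TO3, AA_3TO1
from .dataset import AffinityRecord, Dataset, ThresholdSpec, resistance_threshold
from .learning import ATP_KEY, FeatureConfig, assemble_features
from .ligand_props import MolecularGraph, read_mol
from .structure_io import ComplexRecord, read_pdb

# residues sampled for toy proteins: a diverse mix, no Gly/Pro edge cases in
# the pocket so side-chain truncation is always well defined
_TOY_AA = "ADEFHIKLMNQRSTVWY"

# Ground-truth weights (on z-scored features). Most of the signal sits in
# substitution-level (dpharm) and drug-level (lig) features, which recur
# across residue positions — emulating chemistry-driven resistance that a
# position-exclusive validation scheme can actually generalize to; the
# position-level environment features carry a smaller share.
DEFAULT_WEIGHTS: dict[str, float] = {
    "dpharm:Hydrophobic": 1.0,
    "dpharm:HDonor": -0.6,
    "lig:tpsa": 0.6,
    "env:rel_sasa": 0.4,
    "env:min_dist_ligand": -0.4,
    "sig:Hydrophobic-Hydrophobic:<=6": 0.35,
}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_residues: int = 30
    n_ligand_atoms: int = 8
    n_records: int = 200
    noise_sd: float = 0.3
    resistant_fraction: float = 0.25
    signal_sd: float = 1.5
    weights: tuple = tuple(DEFAULT_WEIGHTS.items())
    n_positions: int = 20

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")


def pocket_index(spec: FixtureSpec, variant: int = 0) -> int:
    """0-based index of the pocket residue a drug variant docks against."""
    return spec.n_residues // 2 + (variant % 3) - 1


def pocket_seqnum(spec: FixtureSpec, variant: int = 0) -> int:
    """PDB residue number (1-based) of the pocket residue."""
    return pocket_index(spec, variant) + 1


def _helix_backbone(n: int) -> list[dict[str, np.ndarray]]:
    rise, twist, radius = 1.5, math.radians(100.0), 2.3
    out = []
    for i in range(n):
        theta = i * twist
        r_hat = np.array([math.cos(theta), math.sin(theta), 0.0])
        t_hat = np.array([-math.sin(theta), math.cos(theta), 0.3])
        t_hat /= np.linalg.norm(t_hat)
        ca = radius * r_hat + np.array([0.0, 0.0, rise * i])
        out.append(
            {
                "N": ca - 0.75 * t_hat,
                "CA": ca,
                "C": ca + 0.75 * t_hat,
                "O": ca + 0.75 * t_hat + 1.23 * r_hat,
                "CB": ca + 1.53 * r_hat,
            }
        )
    return out


def _pdb_lines(residues, ligand, ligand_name="LIG", chain="A",
               first_resnum=1):
    lines = []
    serial = 0
    for i, (aa3, atoms) in enumerate(residues, start=first_resnum):
        for name, xyz in atoms.items():
            if aa3 == "GLY" and name == "CB":
                continue
            serial += 1
            element = name[0]
            lines.append(
                f"ATOM  {serial:>5d}  {name:<3s}{aa3:>4s} {chain}{i:>4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {element:>2s}"
            )
    for j, (element, xyz) in enumerate(ligand, start=1):
        serial += 1
        atom_name = f"{element}{j}"
        lines.append(
            f"HETATM{serial:>5d}  {atom_name:<3s}{ligand_name:>4s} {chain}"
            f"{first_resnum + len(residues) + 700:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _mol_block(ligand, title="toy ligand") -> str:
    n = len(ligand)
    lines = [title, "  ddgscan " + " " * 10 + "3D", "",
             f"{n:>3d}{n - 1:>3d}  0  0  0  0  0  0  0  0999 V2000"]
    for element, xyz in ligand:
        lines.append(
            f"{xyz[0]:>10.4f}{xyz[1]:>10.4f}{xyz[2]:>10.4f} {element:<3s}"
            " 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for i in range(1, n):
        lines.append(f"{i:>3d}{i + 1:>3d}  1  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def make_toy_complex(
    spec: FixtureSpec,
    drug_id: str = "DRUG1",
    binding_mode: str = "type_I",
    variant: int = 0,
    first_resnum: int = 1,
) -> tuple[ComplexRecord, MolecularGraph, str, str]:
    """Build one toy complex; returns (complex, ligand graph, pdb, mol).

    ``variant`` perturbs the ligand composition and pocket placement so that
    different drugs yield different per-drug features under the same seed.
    """
    rng = np.random.default_rng(int(spec.seed) * 1000 + 17 * variant)
    backbone = _helix_backbone(spec.n_residues)
    # one protein, many complexes: the sequence depends on the seed only,
    # never on the drug variant
    seq_rng = np.random.default_rng(int(spec.seed))
    aa_codes = seq_rng.choice(list(_TOY_AA), size=spec.n_residues)
    residues = [(AA_1TO3[aa], atoms) for aa, atoms in zip(aa_codes, backbone)]

    pocket = pocket_index(spec, variant)
    pocket_cb = backbone[pocket]["CB"]
    theta = (pocket + 0.0) * math.radians(100.0)
    out_dir = np.array([math.cos(theta), math.sin(theta), 0.0])
    elements = ["C", "N", "O", "C", "C", "N", "C", "O", "C", "C", "N", "C"]
    k = 1 + (variant % 3)
    elements = elements[k:] + elements[:k]
    start = pocket_cb + 3.5 * out_dir
    ligand = []
    for j in range(spec.n_ligand_atoms):
        jitter = rng.normal(0.0, 0.08, size=3)
        xyz = start + 1.45 * j * out_dir + jitter
        ligand.append((elements[j % len(elements)], xyz))

    pdb_text = _pdb_lines(residues, ligand, first_resnum=first_resnum)
    mol_text = _mol_block(ligand, title=drug_id)
    structure = read_pdb(pdb_text)
    lig_atoms = [a for a in structure.atoms if a.is_het]
    cr = ComplexRecord(
        structure=structure,
        ligand_id=drug_id,
        binding_mode=binding_mode,
        ligand_atoms=lig_atoms,
    )
    return cr, read_mol(mol_text), pdb_text, mol_text


def make_complex_set(
    spec: FixtureSpec, n_drugs: int = 3, include_atp: bool = True
) -> tuple[dict[str, ComplexRecord], dict[str, MolecularGraph], dict[str, tuple[str, str]]]:
    """Toy drug complexes (plus an endogenous-ligand complex) and ligands."""
    complexes: dict[str, ComplexRecord] = {}
    ligands: dict[str, MolecularGraph] = {}
    texts: dict[str, tuple[str, str]] = {}
    modes = ["type_I", "type_II"]
    for d in range(n_drugs):
        drug = f"DRUG{d + 1}"
        cr, g, pdb, mol = make_toy_complex(
            spec, drug_id=drug, binding_mode=modes[d % 2], variant=d
        )
        complexes[drug] = cr
        ligands[drug] = g
        texts[drug] = (pdb, mol)
    if include_atp:
        cr, g, pdb, mol = make_toy_complex(
            spec, drug_id=ATP_KEY, binding_mode="endogenous",
            variant=n_drugs,
        )
        complexes[ATP_KEY] = cr
        ligands[ATP_KEY] = g
        texts[ATP_KEY] = (pdb, mol)
    return complexes, ligands, texts


def _resolve_weight(name: str, columns) -> str:
    if name in columns:
        return name
    # allow threshold spellings like <=6 vs <=6.0
    for c in columns:
        if c.startswith(name):
            return c
    raise KeyError(f"weight feature {name!r} not found among assembled columns")


def make_synthetic_dataset(
    spec: FixtureSpec,
    complexes: dict[str, ComplexRecord],
    ligands: dict[str, MolecularGraph] | None = None,
    config: FeatureConfig | None = None,
    threshold_spec: ThresholdSpec | None = None,
) -> tuple[Dataset, dict]:
    """Sample mutations and simulate ΔΔG with a known linear dependence.

    The named weight features are z-scored over the sampled design, combined
    with the ground-truth weights, rescaled to ``signal_sd`` and offset so
    that the fraction of records at or above the resistance threshold
    approximates ``resistant_fraction``; Gaussian noise of ``noise_sd``
    kcal/mol is added on top. Returns the dataset and a ground-truth dict
    (weights, threshold, signal scale) for parameter-recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    drug_ids = sorted(k for k in complexes if k != ATP_KEY)
    any_cr = complexes[drug_ids[0]]
    seqnums = [
        r.seqnum for r in any_cr.structure.residues
        if not r.atoms[0].is_het and r.name in AA_3TO1
    ]
    inner = seqnums[2:-2]
    n_pos = min(spec.n_positions, len(inner))
    positions = sorted(
        rng.choice(inner, size=n_pos, replace=False).tolist()
    )

    grid = []
    for drug in drug_ids:
        for pos in positions:
            res = next(
                r for r in complexes[drug].structure.residues
                if r.seqnum == pos and not r.atoms[0].is_het
            )
            wt = AA_3TO1[res.name]
            for mt in "ACDEFGHIKLMNPQRSTVWY":
                if mt != wt:
                    grid.append((drug, res.chain, pos, wt, mt))
    if spec.n_records > len(grid):
        raise ValueError("n_records exceeds the available mutation grid")
    idx = rng.choice(len(grid), size=spec.n_records, replace=False)
    chosen = [grid[i] for i in idx]

    records = [
        AffinityRecord(drug_id=d, chain=c, position=p, wt_aa=w, mt_aa=m,
                       ddg=0.0)
        for d, c, p, w, m in chosen
    ]
    X = assemble_features(records, complexes, ligands, config)
    weights = dict(spec.weights)
    resolved = {_resolve_weight(k, X.columns): v for k, v in weights.items()}
    signal = np.zeros(len(records))
    for name, w in resolved.items():
        col = X[name].to_numpy(dtype=float)
        sd = col.std()
        if sd == 0:
            raise ValueError(f"weight feature {name!r} is constant in design")
        signal += w * (col - col.mean()) / sd
    scale = spec.signal_sd / signal.std() if signal.std() > 0 else 1.0
    signal *= scale

    tspec = threshold_spec or ThresholdSpec()
    threshold = resistance_threshold(tspec)
    offset = threshold - np.quantile(signal, 1.0 - spec.resistant_fraction)
    ddg = signal + offset + rng.normal(0.0, spec.noise_sd, size=len(records))

    final = [
        AffinityRecord(
            drug_id=r.drug_id, chain=r.chain, position=r.position,
            wt_aa=r.wt_aa, mt_aa=r.mt_aa, ddg=float(v),
        )
        for r, v in zip(records, ddg)
    ]
    truth = {
        "weights": resolved,
        "signal_scale": float(scale),
        "offset": float(offset),
        "threshold": threshold,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return Dataset(final, provenance=f"synthetic(seed={spec.seed})",
                   seed=spec.seed), truth
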