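"""Shared fixtures: toy complexes and synthetic datasets at two scales."""

from __future__ import annotations

import numpy as np
import pytest

from ddgscan.fixtures import (
    FixtureSpec,
    make_complex_set,
    make_synthetic_dataset,
)
from ddgscan.learning import assemble_features


@pytest.fixture(scope="session")
def study_world():
    """Full-scale synthetic study: 3 drugs + ATP, 200 records, 20 sites."""
    spec = FixtureSpec(seed=1, n_records=200)
    complexes, ligands, texts = make_complex_set(spec)
    data, truth = make_synthetic_dataset(spec, complexes, ligands)
    X = assemble_features(data.records, complexes, ligands)
    y = np.array([r.ddg for r in data])
    return {
        "spec": spec, "complexes": complexes, "ligands": ligands,
        "texts": texts, "data": data, "truth": truth, "X": X, "y": y,
    }


@pytest.fixture(scope="session")
def small_world():
    """Small world for cheap structural tests: 12 residues, 2 drugs."""
    spec = FixtureSpec(seed=5, n_residues=12, n_records=30, n_positions=6)
    complexes, ligands, texts = make_complex_set(spec, n_drugs=2)
    return {"spec": spec, "complexes": complexes, "ligands": ligands,
            "texts": texts}


def make_pdb(atoms) -> str:
    """Tiny PDB writer for hand-built test scenes.

    ``atoms``: tuples of (record, serial, name, resname, chain, resnum,
    x, y, z, occupancy, element[, altloc]).
    """
    lines = []
    for a in atoms:
        rec, serial, name, resname, chain, resnum, x, y, z, occ, elem = a[:11]
        altloc = a[11] if len(a) > 11 else " "
        padded = name if len(name) == 4 else f" {name:<3s}"
        lines.append(
            f"{rec:<6s}{serial:>5d} {padded}{altloc}{resname:>3s} {chain}"
            f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {elem:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
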