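"""In silico saturation mutagenesis.

Applies a trained ΔΔG regressor and resistance classifier to every possible
substitution (19 per position) over a residue range, for every drug complex
— the precomputed scan behind a mutation-lookup service. The kinase-domain
default range 242-493 (inclusive) gives 252 positions and 4,788 rows per
drug when fully resolved.
"""

from __future__ import annotations

import logging
import pandas as pd

from .constants import AA_3TO1, CANONICAL_AA
from .dataset import AffinityRecord
from .learning import ATP_KEY, FeatureConfig, TrainedModel, assemble_features, predict
from .ligand_props import MolecularGraph
from .structure_io import ComplexRecord

logger = logging.getLogger(__name__)


def saturate(
    regressor: TrainedModel,
    classifier: TrainedModel | None,
    complexes: dict[str, ComplexRecord],
    ligands: dict[str, MolecularGraph] | None,
    residue_range: tuple[int, int],
    drugs: list[str] | None = None,
    chain: str | None = None,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Predict ΔΔG and phenotype for all substitutions in a residue range.

    Positions that do not resolve to a standard residue in a given complex
    are skipped with a warning. Endpoints are inclusive.
    """
    start, end = residue_range
    if end < start:
        raise ValueError("empty residue range")
    if drugs is None:
        drugs = sorted(k for k in complexes if k != ATP_KEY)
    rows = []
    pseudo_records: list[AffinityRecord] = []
    for drug in drugs:
        cr = complexes[drug]
        for pos in range(start, end + 1):
            res = _resolve(cr, pos, chain)
            if res is None:
                logger.warning(
                    "position %d unresolved in complex %s; skipped", pos, drug
                )
                continue
            wt = AA_3TO1.get(res.name)
            if wt is None:
                logger.warning(
                    "position %d in complex %s is non-standard (%s); skipped",
                    pos, drug, res.name,
                )
                continue
            for mt in CANONICAL_AA:
                if mt == wt:
                    continue
                pseudo_records.append(
                    AffinityRecord(
                        drug_id=drug, chain=res.chain, position=pos,
                        wt_aa=wt, mt_aa=mt, ddg=0.0,
                    )
                )
    if not pseudo_records:
        raise ValueError("no resolvable positions in range")
    X = assemble_features(pseudo_records, complexes, ligands, config)
    ddg_pred = predict(regressor, X)
    if classifier is not None:
        labels, scores = predict(classifier, X)
    else:
        labels = scores = [None] * len(pseudo_records)
    for rec, ddg, lab, score in zip(pseudo_records, ddg_pred, labels, scores):
        rows.append(
            {
                "drug": rec.drug_id,
                "chain": rec.chain,
                "position": rec.position,
                "wt": rec.wt_aa,
                "mt": rec.mt_aa,
                "predicted_ddg": float(ddg),
                "phenotype": (
                    None if lab is None
                    else ("resistant" if int(lab) == 1 else "susceptible")
                ),
                "classifier_score": None if score is None else float(score),
            }
        )
    return pd.DataFrame(rows)


def _resolve(cr: ComplexRecord, position: int, chain: str | None):
    for res in cr.structure.residues:
        if res.seqnum == position and (chain is None or res.chain == chain):
            if res.atoms and not res.atoms[0].is_het:
                return res
    return None


def to_wide(table: pd.DataFrame, value: str = "predicted_ddg") -> pd.DataFrame:
    """Wide summary: rows are drugs, columns are mutations."""
    t = table.copy()
    t["mutation"] = t["wt"] + t["position"].astype(str) + t["mt"]
    return t.pivot(index="drug", columns="mutation", values=value)
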