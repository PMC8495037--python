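"""Affinity-change records, resistance labelling, augmentation and splits.

The unit of data is one (drug, mutation) pair with a measured or simulated
binding free-energy change ΔΔG (kcal/mol, positive = affinity loss).
A mutation is called resistant when its ΔΔG meets the fold-loss threshold
RT·ln(fold) — 1.36 kcal/mol for a 10-fold loss at 298.15 K.

Validation schemes here are position-exclusive: records sharing a residue
position (site) never straddle a train/test boundary, and leave-one-
position-out cross-validation holds out one site at a time.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

import pandas as pd

from .constants import CANONICAL_AA, GAS_CONSTANT_KCAL, STANDARD_TEMPERATURE_K

RESISTANT = "resistant"
SUSCEPTIBLE = "susceptible"

CSV_COLUMNS = ["drug", "chain", "position", "wt", "mt", "ddg"]


@dataclass(frozen=True)
class ThresholdSpec:
    """Affinity-loss fold threshold with thermodynamic constants."""

    fold: float = 10.0
    R: float = GAS_CONSTANT_KCAL
    T: float = STANDARD_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0:
            raise ValueError("R and T must be positive")


def resistance_threshold(spec: ThresholdSpec) -> float:
    """ΔΔG threshold RT·ln(fold) in kcal/mol."""
    if spec.fold <= 1:
        raise ValueError("fold must exceed 1")
    return spec.R * spec.T * math.log(spec.fold)


def label_record(ddg: float, threshold: float) -> str:
    """Resistant iff ddg >= threshold (boundary inclusive)."""
    if not (math.isfinite(ddg) and math.isfinite(threshold)):
        raise ValueError("ddg and threshold must be finite")
    return RESISTANT if ddg >= threshold else SUSCEPTIBLE


@dataclass(frozen=True)
class AffinityRecord:
    drug_id: str
    chain: str
    position: int
    wt_aa: str
    mt_aa: str
    ddg: float
    is_reverse: bool = False
    label: str | None = None
    binding_mode: str | None = None

    def __post_init__(self) -> None:
        if self.wt_aa == self.mt_aa:
            raise ValueError("wild-type and mutant residues must differ")
        if self.wt_aa not in CANONICAL_AA or self.mt_aa not in CANONICAL_AA:
            raise ValueError(
                f"non-canonical amino acid in {self.wt_aa}->{self.mt_aa}"
            )
        if not math.isfinite(self.ddg):
            raise ValueError("ddg must be finite")

    @property
    def site(self) -> tuple[str, int]:
        return (self.chain, self.position)

    @property
    def mutation(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mt_aa}"

    @property
    def key(self) -> tuple:
        return (self.drug_id, self.position, self.wt_aa, self.mt_aa,
                self.is_reverse)


@dataclass
class Dataset:
    records: list[AffinityRecord] = field(default_factory=list)
    provenance: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (drug, position, wt, mt, reverse) keys")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def positions(self) -> list[tuple[str, int]]:
        return sorted({r.site for r in self.records})

    def forward_only(self) -> "Dataset":
        return Dataset(
            [r for r in self.records if not r.is_reverse],
            provenance=self.provenance, seed=self.seed,
        )

    def with_labels(self, threshold: float) -> "Dataset":
        return Dataset(
            [replace(r, label=label_record(r.ddg, threshold))
             for r in self.records],
            provenance=self.provenance, seed=self.seed,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "drug": r.drug_id, "chain": r.chain,
                    "position": r.position, "wt": r.wt_aa, "mt": r.mt_aa,
                    "ddg": r.ddg, "is_reverse": r.is_reverse,
                    "label": r.label,
                }
                for r in self.records
            ]
        )


def read_affinity_csv(source) -> Dataset:
    """Read the affinity table (drug,chain,position,wt,mt,ddg[,is_reverse])."""
    df = pd.read_csv(source)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"affinity CSV missing columns: {sorted(missing)}")
    records = [
        AffinityRecord(
            drug_id=str(row.drug),
            chain=str(row.chain),
            position=int(row.position),
            wt_aa=str(row.wt),
            mt_aa=str(row.mt),
            ddg=float(row.ddg),
            is_reverse=bool(getattr(row, "is_reverse", False)),
        )
        for row in df.itertuples(index=False)
    ]
    name = getattr(source, "name", None) or (
        source if isinstance(source, str) else "<buffer>"
    )
    return Dataset(records, provenance=f"csv:{name}")


def write_affinity_csv(d: Dataset, target) -> None:
    df = d.to_frame().drop(columns=["label"])
    df.to_csv(target, index=False)


def augment_reverse(d: Dataset) -> Dataset:
    """Add the hypothetical reverse mutation of every forward record.

    Each WT→MT record with ΔΔG gains a MT→WT twin with −ΔΔG; output size is
    exactly twice the input. Refuses datasets that already contain reverse
    records, so augmentation cannot be applied twice.
    """
    if any(r.is_reverse for r in d.records):
        raise ValueError("dataset already contains reverse records")
    reverses = [
        replace(r, wt_aa=r.mt_aa, mt_aa=r.wt_aa, ddg=-r.ddg,
                is_reverse=True, label=None)
        for r in d.records
    ]
    return Dataset(
        d.records + reverses,
        provenance=f"{d.provenance}+reverse",
        seed=d.seed,
    )


def split_by_position(
    d: Dataset,
    test_positions: set[tuple[str, int]] | None = None,
    test_fraction: float | None = None,
    seed: int | None = None,
) -> tuple[Dataset, Dataset]:
    """Partition records so train and test share no residue position.

    Either an explicit test-position set or a target record fraction is
    given; with a fraction, positions are shuffled with the seed and greedily
    assigned to the test side until the fraction is reached.
    """
    sites = d.positions()
    if len(sites) < 2:
        raise ValueError("need at least two distinct positions to split")
    if (test_positions is None) == (test_fraction is None):
        raise ValueError("give exactly one of test_positions / test_fraction")
    if test_fraction is not None:
        if not (0 < test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        rng = random.Random(seed)
        shuffled = sites[:]
        rng.shuffle(shuffled)
        per_site = {s: sum(1 for r in d.records if r.site == s) for s in sites}
        target = test_fraction * len(d.records)
        chosen: set[tuple[str, int]] = set()
        got = 0
        for s in shuffled:
            if got >= target:
                break
            if len(sites) - len(chosen) <= 1:
                break  # keep at least one training position
            chosen.add(s)
            got += per_site[s]
        if not chosen:
            raise ValueError("test fraction unreachable with these positions")
        test_positions = chosen
    else:
        # bare integers are accepted and match the position on any chain
        test_positions = {
            p if isinstance(p, tuple) else next(
                (s for s in sites if s[1] == p), ("", p)
            )
            for p in test_positions
        }
        if not test_positions or not (set(sites) - test_positions):
            raise ValueError("test positions must be a proper non-empty subset")
    train = [r for r in d.records if r.site not in test_positions]
    test = [r for r in d.records if r.site in test_positions]
    return (
        Dataset(train, provenance=f"{d.provenance}|train", seed=seed),
        Dataset(test, provenance=f"{d.provenance}|test", seed=seed),
    )


def grouped_kfold(
    d: Dataset, k: int = 10, seed: int | None = None
) -> list[tuple[int, list[int], list[int]]]:
    """Position-exclusive k-fold scheme: sites are dealt round-robin into k
    groups after a seeded shuffle, so no site straddles a fold boundary.
    Used as the (cheaper) inner CV for greedy feature selection."""
    sites = d.positions()
    if len(sites) < k:
        raise ValueError(f"need >= {k} positions for {k}-fold grouping")
    rng = random.Random(seed)
    shuffled = sites[:]
    rng.shuffle(shuffled)
    assignment = {s: i % k for i, s in enumerate(shuffled)}
    folds = []
    for g in range(k):
        val = [i for i, r in enumerate(d.records) if assignment[r.site] == g]
        train = [i for i, r in enumerate(d.records) if assignment[r.site] != g]
        folds.append((g, train, val))
    return folds


def lopo_folds(d: Dataset) -> list[tuple[tuple[str, int], list[int], list[int]]]:
    """Leave-one-position-out folds as (site, train indices, val indices)."""
    sites = d.positions()
    if len(sites) < 2:
        raise ValueError("leave-one-position-out needs >= 2 positions")
    folds = []
    for site in sites:
        val = [i for i, r in enumerate(d.records) if r.site == site]
        train = [i for i, r in enumerate(d.records) if r.site != site]
        folds.append((site, train, val))
    return folds
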