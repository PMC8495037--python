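"""Graph-based signatures: cumulative pharmacophore-pair distance counts.

A mutation-site environment is modelled as a graph whose nodes are heavy
atoms with pharmacophore labels and whose edges are interatomic distances.
For each unordered pair of the seven classes and each distance threshold,
the signature counts atom pairs whose distance falls within the threshold —
a cumulative cutoff-scanning distribution (counts never decrease as the
threshold grows).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .pharmacophore import CLASS_INDEX, CLASSES, AtomLabeling
from .structure_io import Atom

# 28 unordered pairs of the 7 classes, in a fixed order.
CLASS_PAIRS: tuple[tuple[str, str], ...] = tuple(
    combinations_with_replacement(CLASSES, 2)
)
PAIR_INDEX = {p: i for i, p in enumerate(CLASS_PAIRS)}


@dataclass(frozen=True)
class SignatureSpec:
    """Distance-threshold grid and environment radius for signatures."""

    d_min: float = 0.0
    d_max: float = 10.0
    step: float = 2.0
    environment_radius: float = 10.0
    include_ligand: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.d_min < self.d_max):
            raise ValueError("require 0 <= d_min < d_max")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not self.thresholds:
            raise ValueError("empty threshold grid")

    @property
    def thresholds(self) -> tuple[float, ...]:
        out = []
        t = self.d_min + self.step
        while t <= self.d_max + 1e-9:
            out.append(round(t, 6))
            t += self.step
        return tuple(out)


@dataclass
class SignatureVector:
    counts: np.ndarray  # shape (28, n_thresholds)
    spec: SignatureSpec
    site: str = ""

    def flat(self) -> np.ndarray:
        return self.counts.reshape(-1)


def compute_signature(
    atoms: list[Atom], labeling: AtomLabeling, spec: SignatureSpec,
    site: str = "",
) -> SignatureVector:
    """Cumulative class-pair counts over all atom pairs within d_max.

    Each unordered atom pair contributes once per distinct unordered class
    pair formed from its two label sets, at every threshold >= its distance.
    """
    thresholds = np.array(spec.thresholds)
    counts = np.zeros((len(CLASS_PAIRS), len(thresholds)), dtype=int)
    if len(atoms) >= 2:
        xyz = np.array([a.coords for a in atoms])
        dmat = squareform(pdist(xyz))
        labels = [labeling[id(a)] for a in atoms]
        n = len(atoms)
        for i in range(n):
            li = labels[i]
            for j in range(i + 1, n):
                d = dmat[i, j]
                if d > spec.d_max:
                    continue
                bin_idx = int(np.searchsorted(thresholds, d - 1e-9))
                if bin_idx >= len(thresholds):
                    continue
                pairs = {
                    tuple(sorted((ca, cb), key=CLASS_INDEX.__getitem__))
                    for ca in li for cb in labels[j]
                }
                for p in pairs:
                    counts[PAIR_INDEX[p], bin_idx:] += 1
    return SignatureVector(counts=counts, spec=spec, site=site)


def signature_feature_names(spec: SignatureSpec) -> list[str]:
    """Deterministic flat feature names, aligned with SignatureVector.flat()."""
    return [
        f"sig:{a}-{b}:<={t:g}"
        for (a, b) in CLASS_PAIRS
        for t in spec.thresholds
    ]
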