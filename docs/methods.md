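# Methods

## Model overview

`ddgscan` treats mutation-induced binding-affinity change as a supervised
learning problem on structural features of the *wild-type* complex plus a
coarse description of the substitution. No mutant structure is ever built;
the mutation enters through (a) signed pharmacophore-count changes of the
substituted residue and (b) contact deltas computed against a truncated
mutant model (below). This keeps every feature cheap, deterministic and
free of conformational sampling, at the cost of ignoring backbone
rearrangement and side-chain repacking — the dominant known failure mode
for mutations that act allosterically.

## Structure handling

PDB input is parsed through gemmi with a validation pre-scan that reports
malformed coordinate fields by line number. Only model 1 is kept; waters
(HOH/WAT/DOD) and hydrogens are dropped; all geometry is heavy-atom only.
Alternate locations resolve deterministically: altloc `A` (or blank) wins,
otherwise the highest-occupancy conformer. Residues keep PDB author
numbering with insertion codes, so positions quoted in kinase numbering
(e.g. 242–493 for the ABL1 kinase domain) map directly.

Solvent accessibility is Shrake–Rupley with a Fibonacci-lattice sphere
sampling: probe 1.4 Å, 960 points per atom, Bondi van der Waals radii
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å). 960 points put the isolated-
atom quadrature error well under 1%, and the lattice makes the estimate
deterministic. Relative accessibility divides by theoretical Gly-X-Gly
maxima (Tien et al. 2013). The implementation is in-package and is tested
against the analytic sphere area and brute-force burial constructions.

## Pharmacophore typing

Seven classes — Hydrophobic, Positive, Negative, HAcceptor, HDonor,
Aromatic, Neutral — in a fixed order that defines all vector layouts. The
protein rule table is shipped as data
(`src/ddgscan/data/pharmacophore_rules.csv`, version `ddgscan-rules-v1`):
every label decision for a protein heavy atom traces to one row; unknown
atoms degrade to Neutral with a warning. Atoms may carry several labels
(Lys NZ is Positive and HDonor; His ND1/NE2 are Positive, Aromatic and
HDonor, reflecting its pH ambiguity), and multi-label atoms contribute once
per label to counts and signature pairs. The exact table is a design choice
— published atom-typing schemes in this lineage are not fully specified —
so tests pin the shipped table, not the literature. Ligand (het) atoms,
which arrive without bond orders, are typed by element: C/S/halogens
hydrophobic, N donor+acceptor, O acceptor, metals positive.

Per-residue class counts come from idealized heavy-atom topologies
(backbone N/CA/C/O plus standard side-chain atom names); the substitution
feature is the componentwise difference Δn = n(mut) − n(wt), which is
antisymmetric by construction.

## Graph-based signatures

For the atoms within the environment radius of the mutation site (default
10 Å, ligand atoms included by default — both configurable), every
unordered atom pair within `d_max` contributes one count per distinct
unordered class pair formed from its two label sets, at every threshold ≥
its distance. Defaults: thresholds 2, 4, 6, 8, 10 Å (`d_min` 0, step 2),
giving 28 class pairs × 5 thresholds = 140 cumulative features. Signatures
are computed on the wild-type environment only; the mutation is encoded by
the Δ-pharmacophore and Δ-contact features instead. Cumulativity,
rigid-motion invariance and exact agreement with an independent O(n²)
brute-force counter are tested.

## Interatomic contacts

Seven contact types with distance-only criteria (X-ray inputs lack
hydrogens, so angle terms are deliberately omitted): hydrogen bond
(donor–acceptor heavy atoms ≤ 3.5 Å), van der Waals clash
(d < r₁ + r₂ − 0.1 Å), ionic (≤ 4.0 Å), hydrophobic (two hydrophobic
carbons ≤ 4.5 Å), carbon–π (carbon to aromatic ring centroid ≤ 4.5 Å),
amide–ring (backbone N/C/O centroid to ring centroid ≤ 4.5 Å), ring–ring
(centroids ≤ 5.5 Å). The criteria live in an editable table. Protein rings
come from residue templates (Trp contributes two); het-group rings from
geometric 5/6-cycle perception on C/N atoms with a 1.75 Å bond cutoff.
Contacts are counted separately for the site-residue↔ligand and
site-residue↔protein scopes.

The mutant model is a common-atom truncation: the site residue keeps its
backbone plus the side-chain atoms shared by both topologies (worst case
Cβ) and is renamed; mutations to larger residues build nothing and log a
warning. This biases Δ-contacts toward loss terms, which is acceptable for
a feature (the learner can use the bias) but is not a physical model. A
user-supplied mutant structure can be used instead.

## Ligand descriptors

RDKit supplies the chemistry behind a thin, stable surface: Ertl TPSA
(S/P-inclusive by default, switchable), rotatable bonds, SSSR ring count,
Lipinski H-bond donors/acceptors, heavy-atom count, optional Crippen logP.
Positively ionizable centres are counted as non-aromatic basic nitrogens
(excluding amide/sulfonamide-adjacent and heteroatom-bonded ones) plus one
per amidine/guanidine group. SMILES input goes through an adapter; the
native format is SDF/MOL V2000.

## Dataset semantics

The resistance threshold is RT·ln(fold) with R = 1.9872×10⁻³
kcal·mol⁻¹·K⁻¹ and T = 298.15 K: 1.36 kcal/mol at 10-fold, 0.95 at 5-fold,
boundary inclusive (ΔΔG = threshold ⇒ resistant). Reverse augmentation adds
one MT→WT record with −ΔΔG per forward record and refuses to run twice; it
is intended for regressor training only — the classifier always trains on
forward records, because reverse mutations do not add resistant examples.
Position-exclusive splits group records by (chain, position):
leave-one-position-out CV yields one fold per site; fractional blind splits
shuffle sites with the seed and assign greedily. A position-grouped k-fold
scheme is provided as a cheaper inner loop for feature selection (the
choice of selection CV is genuinely open; we use grouped 5-fold with small
forests for affordability and keep it a parameter).

## Learning

Backends are scikit-learn: Extra-Trees/Random-Forest ensembles, MLP and SVM
behind one config. Defaults are library defaults with a fixed seed, with
one deviation: the Random-Forest classifier uses `class_weight="balanced"`,
because resistance labels are heavily imbalanced and the validation scheme
(one site per fold) cannot be stratified. SVM classification is wrapped in
probability calibration to expose scores.

Greedy selection starts from the empty set, adds the candidate with the
best pooled CV metric each round, stops at no improvement or a feature cap,
breaks ties lexicographically, and skips constant columns (they cannot
change any prediction). CV metrics are pooled over out-of-fold predictions
— one number per scheme, not a per-fold average. For regression, companion
metrics after dropping the 10% largest-error records are reported alongside
and never used for selection. MCC of a degenerate confusion matrix is 0 by
convention; Kendall's tau is tau-b; AUC is the rank statistic.

## Synthetic study (what the generator does and does not emulate)

The generator builds a deterministic toy world: backbone on an ideal helix
(rise 1.5 Å, 100°/residue, radius 2.3 Å), one Cβ pseudo-side-chain per
residue, a seeded sequence shared by all complexes of a study, and per-drug
ligands — short C/N/O chains docked 3–5 Å from a pocket residue, with an
extra complex standing in for the endogenous ligand. Defaults: 30 residues,
20 mutated sites, 3 drugs + endogenous complex, 200 records, mirroring the
scale of the real study (19 sites, 144 measurements) with a higher
resistant fraction (0.25) so every validation fold sees both classes.

ΔΔG is planted as a linear signal on z-scored named features, scaled to
1.5 kcal/mol SD, offset so the resistant fraction hits its target, plus
Normal(0, 0.3 kcal/mol) noise. Most of the weight sits on substitution-
and drug-level features (Δ-pharmacophore counts, TPSA) with smaller
position-level terms — emulating chemistry-driven resistance that
transfers across sites, which is precisely what position-exclusive
validation can detect. What the toy world does *not* emulate: real side
chains and rotamers, backbone flexibility, realistic ligand chemistry,
allosteric effects, or any correlation structure between sites. Passing
recovery tests therefore demonstrates that the pipeline recovers a
transferable structural signal at realistic noise; it says nothing about
accuracy on experimental data, which is bounded by physics the features do
not capture.

One structural caveat: a linear ground truth cannot survive reverse
augmentation. A forward record and its reverse share all position-level
features but need opposite targets, so the augmented synthetic task is
ill-posed by construction; the recovery benchmark therefore runs on forward
records, and augmentation is verified by its own arithmetic/antisymmetry
properties.

## Recovery benchmark protocol and problem sizes

`ddgscan.benchmark.recovery_benchmark(seed)`: 200 forward records; greedy
selection under position-grouped 5-fold CV with 20-tree forests, capped at
8 features; evaluation by pooled leave-one-position-out CV with default
model configs and a position-exclusive 30% blind split. The whole run takes
on the order of a minute on one CPU. At seed 1 the regressor recovers the
planted signal with pooled LOPO Pearson ≈ 0.94 and blind Pearson ≈ 0.91
(the acceptance script recomputes these at any seed).

The classifier is structurally weaker on this task: labels are a hard
threshold on noisy ΔΔG, so records within ~±2 noise SD of 1.36 kcal/mol
carry near-random labels, and even the Bayes classifier built from the true
noiseless signal does not reliably exceed MCC 0.8 under these conditions.
The package reports the classifier's pooled LOPO MCC/F1/BACC/AUC honestly
(≈ 0.61 / 0.72 / 0.83 / 0.89 at seed 1) rather than tuning the generator's
effect-size spread beyond realistic ranges to manufacture a separation
margin.

## Numerical and degenerate-input choices

Distance comparisons carry a 1e-9 tolerance so exact-threshold pairs count
as inside. Signature bins use half-open searchsorted placement into
cumulative bins. Greedy ties break on feature name; constant targets and
empty folds are errors. SASA on unknown elements fails loudly listing the
element. Saturation skips unresolved or non-standard positions with a
warning and reports exactly (#resolved positions) × 19 × (#drugs) rows;
phenotype (classifier) and ΔΔG (regressor) are reported independently and
may disagree — no reconciliation rule is invented.

## Known limitations

* Truncation mutants cannot express gained contacts; Δ-contact features
  are loss-biased.
* Distance-only contact criteria over-count relative to angle-aware
  detectors, particularly hydrogen bonds and carbon–π.
* The ligand atom-typing of het groups is element-level only; signature
  edges involving ligand atoms are correspondingly coarse.
* External predictor scores (stability, conservation, flexibility tools)
  are accepted only as optional precomputed columns; none are
  reimplemented, so feature sets are smaller than a full replication of
  the original study.
* The saturation scan assumes the wild-type structure is valid for every
  substitution at every position; heavily destabilizing mutations violate
  this silently.
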