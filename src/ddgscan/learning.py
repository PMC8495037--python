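"""Feature assembly, greedy selection, model training and evaluation.

Feature matrix columns fall into four groups:

1. ligand descriptors (``lig:*``) and the ligand-to-site distance;
2. mutation-site environment: relative solvent accessibility and the signed
   pharmacophore-count change of the substitution (``dpharm:*``);
3. typed interatomic contacts of the wild-type site (``wtct:<scope>:*``) and
   wild-type-minus-mutant deltas (``dct:<scope>:*``), against the drug and —
   when an endogenous-ligand complex is supplied — against ATP (``atp*``);
4. graph-based signatures of the wild-type environment (``sig:*``).

Models are scikit-learn ensembles/networks behind a small config; feature
selection is bottom-up greedy under a cross-validation scheme, scored by
Pearson's r (regression) or Matthews correlation (classification).
Cross-validation metrics are pooled over out-of-fold predictions, one number
per scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR

from .dataset import AffinityRecord
from .interactions import (
    CONTACT_TYPES,
    ContactSummary,
    contact_summary,
    delta_contacts,
    mutant_environment,
)
from .ligand_props import MolecularGraph, compute_descriptors
from .pharmacophore import CLASSES, delta_pharmacophore, label_structure
from .signatures import SignatureSpec, compute_signature, signature_feature_names
from .structure_io import (
    ComplexRecord,
    get_environment,
    min_distance_to_ligand,
    shrake_rupley_sasa,
)

# ---------------------------------------------------------------------------
# metrics — thin wrappers fixing the package-wide conventions
# ---------------------------------------------------------------------------


def _check_lengths(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least two observations")
    return a, b


def pearson(a, b) -> float:
    a, b = _check_lengths(a, b)
    return float(np.corrcoef(a, b)[0, 1])


def spearman(a, b) -> float:
    a, b = _check_lengths(a, b)
    return float(sps.spearmanr(a, b).statistic)


def kendall_tau(a, b) -> float:
    """Tau-b (tie-corrected)."""
    a, b = _check_lengths(a, b)
    return float(sps.kendalltau(a, b, variant="b").statistic)


def rmse(a, b) -> float:
    a, b = _check_lengths(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mcc(cm) -> float:
    """Matthews correlation from a 2x2 confusion matrix [[TN,FP],[FN,TP]].

    A degenerate matrix (any zero margin) yields 0 by convention.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (2, 2):
        raise ValueError("confusion matrix must be 2x2")
    tn, fp, fn, tp = cm.ravel()
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def f1(cm) -> float:
    """F1 with the resistant (positive) class in the TP cell."""
    cm = np.asarray(cm, dtype=float)
    tn, fp, fn, tp = cm.ravel()
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 0.0


def bacc(cm) -> float:
    cm = np.asarray(cm, dtype=float)
    tn, fp, fn, tp = cm.ravel()
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return float((sens + spec) / 2)


def auc(scores, labels) -> float:
    """ROC AUC via the rank (Mann-Whitney) statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("length mismatch")
    return float(roc_auc_score(labels, scores))


def confusion(y_true, y_pred) -> np.ndarray:
    return confusion_matrix(y_true, y_pred, labels=[0, 1])


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

ATP_KEY = "ATP"


@dataclass
class FeatureConfig:
    signature_spec: SignatureSpec = field(default_factory=SignatureSpec)
    sasa_points: int = 960
    contact_radius: float = 10.0


class _ComplexCache:
    """Per-complex precomputation shared across records and positions."""

    def __init__(self, complex_record: ComplexRecord, config: FeatureConfig):
        self.cr = complex_record
        self.config = config
        self.labeling = label_structure(complex_record.structure)
        self.sasa = shrake_rupley_sasa(
            complex_record.structure, n_points=config.sasa_points
        )
        self._env: dict = {}
        self._wt_contacts: dict = {}
        self._mt_contacts: dict = {}

    def resolve(self, position: int, chain: str | None = None):
        s = self.cr.structure
        for res in s.residues:
            if res.seqnum == position and not res.atoms[0].is_het and (
                chain is None or res.chain == chain
            ):
                return res
        return None

    def site_features(self, chain: str, position: int) -> dict[str, float] | None:
        key = (chain, position)
        if key in self._env:
            return self._env[key]
        res = self.resolve(position, chain)
        if res is None:
            self._env[key] = None
            return None
        s = self.cr.structure
        spec = self.config.signature_spec
        env = get_environment(
            s, chain, position, spec.environment_radius,
            include_self=True, include_het=spec.include_ligand,
        )
        sig = compute_signature(env, self.labeling, spec,
                                site=f"{chain}{position}")
        rel = self.sasa[res.key]["relative"]
        feats = {
            "env:min_dist_ligand": min_distance_to_ligand(
                s, chain, position, self.cr.ligand_atoms
            ),
            "env:rel_sasa": rel if rel is not None else 0.0,
        }
        for name, v in zip(signature_feature_names(spec), sig.flat()):
            feats[name] = float(v)
        self._env[key] = feats
        return feats

    def wt_contacts(self, chain: str, position: int) -> ContactSummary:
        key = (chain, position)
        if key not in self._wt_contacts:
            self._wt_contacts[key] = contact_summary(
                self.cr.structure, chain, position, self.cr.ligand_atoms,
                self.labeling, radius=self.config.contact_radius,
            )
        return self._wt_contacts[key]

    def mt_contacts(self, chain: str, position: int, mt: str) -> ContactSummary:
        key = (chain, position, mt)
        if key not in self._mt_contacts:
            mut = mutant_environment(self.cr.structure, chain, position, mt)
            labeling = label_structure(mut)
            lig = [a for a in mut.atoms if a.is_het]
            self._mt_contacts[key] = contact_summary(
                mut, chain, position, lig, labeling,
                radius=self.config.contact_radius,
            )
        return self._mt_contacts[key]


def _contact_features(prefix: str, summary: ContactSummary) -> dict[str, float]:
    return {
        f"{prefix}:{scope}:{t}": float(summary.counts[scope][t])
        for scope in sorted(summary.counts)
        for t in CONTACT_TYPES
    }


def assemble_features(
    records: list[AffinityRecord],
    complexes: dict[str, ComplexRecord],
    ligands: dict[str, MolecularGraph] | None = None,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """One feature row per affinity record.

    ``complexes`` maps drug id to its complex; an entry under ``"ATP"`` is
    treated as the endogenous-ligand complex and contributes ATP-relative
    columns to every row. ``ligands`` maps drug id to a parsed molecular
    graph for descriptor columns.
    """
    if config is None:
        config = FeatureConfig()
    caches: dict[str, _ComplexCache] = {}

    def cache_for(drug: str) -> _ComplexCache:
        if drug not in caches:
            if drug not in complexes:
                raise KeyError(f"no complex for drug id {drug!r}")
            caches[drug] = _ComplexCache(complexes[drug], config)
        return caches[drug]

    lig_desc: dict[str, dict[str, float]] = {}
    if ligands:
        for drug, g in ligands.items():
            lig_desc[drug] = compute_descriptors(g).as_features()

    atp_cache = cache_for(ATP_KEY) if ATP_KEY in complexes else None

    rows = []
    for rec in records:
        cache = cache_for(rec.drug_id)
        row: dict[str, float] = {}
        if rec.drug_id in lig_desc:
            row.update(lig_desc[rec.drug_id])
        site = cache.site_features(rec.chain, rec.position)
        if site is None:
            raise KeyError(
                f"position {rec.chain}/{rec.position} unresolved in complex "
                f"{rec.drug_id}"
            )
        row.update(site)
        for cls, v in zip(CLASSES, delta_pharmacophore(rec.wt_aa, rec.mt_aa)):
            row[f"dpharm:{cls}"] = float(v)
        wt = cache.wt_contacts(rec.chain, rec.position)
        mt = cache.mt_contacts(rec.chain, rec.position, rec.mt_aa)
        row.update(_contact_features("wtct", wt))
        for scope, per_type in delta_contacts(wt, mt).items():
            for t, v in per_type.items():
                row[f"dct:{scope}:{t}"] = float(v)
        if atp_cache is not None:
            atp_site = atp_cache.site_features(rec.chain, rec.position)
            if atp_site is not None:
                row["atp:min_dist_ligand"] = atp_site["env:min_dist_ligand"]
                wt_atp = atp_cache.wt_contacts(rec.chain, rec.position)
                row.update({
                    f"atpct:{scope}:{t}": float(wt_atp.counts[scope][t])
                    for scope in sorted(wt_atp.counts)
                    for t in CONTACT_TYPES
                })
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values after assembly in columns: {bad}")
    return df


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

ALGORITHMS = ("extra_trees", "random_forest", "mlp", "svm")


@dataclass(frozen=True)
class ModelConfig:
    task: str = "regression"  # or "classification"
    algorithm: str = "extra_trees"
    seed: int = 0
    hyperparameters: tuple = ()

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def hp(self) -> dict:
        return dict(self.hyperparameters)


def make_model(config: ModelConfig):
    hp = config.hp
    reg = config.task == "regression"
    if config.algorithm == "extra_trees":
        cls = ExtraTreesRegressor if reg else ExtraTreesClassifier
        return cls(random_state=config.seed, **hp)
    if config.algorithm == "random_forest":
        if reg:
            return RandomForestRegressor(random_state=config.seed, **hp)
        # resistance data are heavily imbalanced; class weighting stands in
        # for the stratification the validation scheme cannot provide
        hp.setdefault("class_weight", "balanced")
        return RandomForestClassifier(random_state=config.seed, **hp)
    if config.algorithm == "mlp":
        cls = MLPRegressor if reg else MLPClassifier
        return cls(random_state=config.seed, **hp)
    if reg:
        return SVR(**hp)
    # probability calibration wrapper gives SVC a predict_proba surface
    from sklearn.calibration import CalibratedClassifierCV

    return CalibratedClassifierCV(SVC(random_state=config.seed, **hp),
                                  ensemble=False)


@dataclass
class TrainedModel:
    estimator: object
    feature_names: list[str]
    config: ModelConfig
    metadata: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.estimator, directory / "model.joblib")
        manifest = {
            "feature_names": self.feature_names,
            "config": {
                "task": self.config.task,
                "algorithm": self.config.algorithm,
                "seed": self.config.seed,
                "hyperparameters": list(self.config.hyperparameters),
            },
            "metadata": self.metadata,
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        cfg = manifest["config"]
        return cls(
            estimator=joblib.load(directory / "model.joblib"),
            feature_names=manifest["feature_names"],
            config=ModelConfig(
                task=cfg["task"], algorithm=cfg["algorithm"], seed=cfg["seed"],
                hyperparameters=tuple(tuple(x) for x in cfg["hyperparameters"]),
            ),
            metadata=manifest["metadata"],
        )


def train(X: pd.DataFrame, y, config: ModelConfig,
          feature_names: list[str] | None = None) -> TrainedModel:
    if X.empty:
        raise ValueError("empty feature matrix")
    names = list(feature_names) if feature_names else list(X.columns)
    est = make_model(config)
    yv = np.asarray(y)
    est.fit(X[names].to_numpy(), yv)
    return TrainedModel(estimator=est, feature_names=names, config=config)


def predict(model: TrainedModel, X: pd.DataFrame):
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise ValueError(f"feature matrix missing columns: {missing}")
    Z = X[model.feature_names].to_numpy()
    if model.config.task == "regression":
        return model.estimator.predict(Z)
    labels = model.estimator.predict(Z)
    proba = model.estimator.predict_proba(Z)
    pos = list(model.estimator.classes_).index(1)
    return labels, proba[:, pos]


# ---------------------------------------------------------------------------
# greedy forward selection and cross-validated evaluation
# ---------------------------------------------------------------------------


def _pooled_cv_metric(X, y, folds, metric, model_factory, columns) -> float:
    preds = np.empty(len(y), dtype=float)
    yv = np.asarray(y)
    Z = X[columns].to_numpy()
    for _site, train_idx, val_idx in folds:
        est = model_factory()
        est.fit(Z[train_idx], yv[train_idx])
        preds[val_idx] = est.predict(Z[val_idx])
    if metric == "pearson":
        if np.std(preds) == 0 or np.std(yv) == 0:
            return 0.0
        return pearson(preds, yv)
    return mcc(confusion(yv.astype(int), preds.astype(int)))


def greedy_select(
    X: pd.DataFrame,
    y,
    cv: list[tuple],
    metric: str,
    model_factory,
    max_features: int | None = None,
) -> list[str]:
    """Bottom-up greedy feature selection under a CV scheme.

    Starting from the empty set, every round scores each remaining candidate
    added to the current set by the pooled CV metric and keeps the best;
    stops when no candidate improves the score or ``max_features`` is
    reached. Always returns at least one feature. Ties break on the
    lexicographically smaller feature name. Constant columns can never
    change a prediction and are excluded from the candidate pool.
    """
    if metric not in ("pearson", "mcc"):
        raise ValueError("metric must be 'pearson' or 'mcc'")
    yv = np.asarray(y)
    if len(np.unique(yv)) < 2:
        raise ValueError("target is constant")
    if len(cv) < 2:
        raise ValueError("need at least two folds")
    selected: list[str] = []
    best_score = -np.inf
    candidates = sorted(c for c in X.columns if X[c].nunique() > 1)
    if not candidates:
        raise ValueError("all candidate features are constant")
    limit = max_features or len(candidates)
    trajectory: list[float] = []
    while len(selected) < limit:
        round_best, round_name = -np.inf, None
        for name in candidates:
            if name in selected:
                continue
            score = _pooled_cv_metric(
                X, yv, cv, metric, model_factory, selected + [name]
            )
            if score > round_best:
                round_best, round_name = score, name
        if round_name is None:
            break
        if selected and round_best <= best_score:
            break
        selected.append(round_name)
        best_score = round_best
        trajectory.append(round_best)
    greedy_select.last_trajectory = trajectory  # introspection aid
    return selected


@dataclass
class MetricsReport:
    task: str
    pooled: dict[str, float]
    per_fold_sizes: list[int]
    trimmed: dict[str, float] | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "task": self.task,
                "pooled": self.pooled,
                "per_fold_sizes": self.per_fold_sizes,
                "trimmed": self.trimmed,
            },
            indent=2,
        )


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    return {
        "pearson": pearson(y_pred, y_true),
        "spearman": spearman(y_pred, y_true),
        "kendall_tau": kendall_tau(y_pred, y_true),
        "rmse": rmse(y_pred, y_true),
    }


def classification_metrics(y_true, y_pred, scores) -> dict[str, float]:
    cm = confusion(np.asarray(y_true, int), np.asarray(y_pred, int))
    return {
        "mcc": mcc(cm),
        "f1": f1(cm),
        "bacc": bacc(cm),
        "auc": auc(scores, y_true),
    }


def evaluate_cv(
    X: pd.DataFrame,
    y,
    folds: list[tuple],
    config: ModelConfig,
    selected: list[str] | None = None,
    trim_fraction: float = 0.1,
) -> MetricsReport:
    """Pooled out-of-fold metrics under a fold scheme.

    Out-of-fold predictions are pooled across folds and metrics computed on
    the pooled vector — one number per scheme. For regression, a companion
    set of metrics after dropping the ``trim_fraction`` records with largest
    absolute error is reported alongside (never used for selection).
    """
    yv = np.asarray(y)
    names = list(selected) if selected else list(X.columns)
    Z = X[names].to_numpy()
    preds = np.empty(len(yv), dtype=float)
    scores = np.empty(len(yv), dtype=float)
    sizes = []
    for _site, train_idx, val_idx in folds:
        if not len(val_idx) or not len(train_idx):
            raise ValueError("empty fold")
        est = make_model(config)
        est.fit(Z[train_idx], yv[train_idx])
        if config.task == "regression":
            preds[val_idx] = est.predict(Z[val_idx])
        else:
            preds[val_idx] = est.predict(Z[val_idx])
            pos = list(est.classes_).index(1)
            scores[val_idx] = est.predict_proba(Z[val_idx])[:, pos]
        sizes.append(len(val_idx))
    if sum(sizes) != len(yv):
        raise ValueError("folds do not partition the dataset")
    if config.task == "regression":
        pooled = regression_metrics(yv, preds)
        err = np.abs(preds - yv)
        keep = err <= np.quantile(err, 1 - trim_fraction)
        trimmed = (
            regression_metrics(yv[keep], preds[keep]) if keep.sum() >= 2 else None
        )
        return MetricsReport("regression", pooled, sizes, trimmed)
    pooled = classification_metrics(yv.astype(int), preds.astype(int), scores)
    return MetricsReport("classification", pooled, sizes)
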