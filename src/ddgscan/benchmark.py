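"""Parameter-recovery benchmark on the synthetic study.

This is the package's stand-in for performance numbers that would otherwise
require the external mutation/affinity compilation and PDB downloads: a
synthetic study with a known linear ΔΔG dependence is generated, the full
pipeline (feature assembly, greedy selection, training) is run, and the
recovered cross-validated performance is reported.

Protocol (fixed):

* forward records only (the synthetic linear truth is defined on forward
  substitutions; see docs/methods.md for why reverse augmentation is
  incompatible with a linear oracle);
* bottom-up greedy selection under position-grouped 5-fold CV with small
  forests (20 trees), capped at 8 features — Pearson metric for the
  regressor, Matthews correlation for the classifier;
* evaluation: pooled leave-one-position-out CV with the default model
  configurations, plus a position-exclusive 30% blind split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor, RandomForestClassifier

from .dataset import grouped_kfold, lopo_folds, split_by_position
from .fixtures import FixtureSpec, make_complex_set, make_synthetic_dataset
from .learning import (
    ModelConfig,
    assemble_features,
    evaluate_cv,
    greedy_select,
    make_model,
    pearson,
)

SELECTION_TREES = 20
SELECTION_FOLDS = 5
MAX_SELECTED = 8
BLIND_FRACTION = 0.3


def recovery_benchmark(seed: int, n_records: int = 200) -> dict:
    """Run the full synthetic recovery study; returns pooled metrics."""
    spec = FixtureSpec(seed=seed, n_records=n_records)
    complexes, ligands, _ = make_complex_set(spec)
    data, truth = make_synthetic_dataset(spec, complexes, ligands)
    X = assemble_features(data.records, complexes, ligands)
    y = np.array([r.ddg for r in data])
    thr = truth["threshold"]

    inner = grouped_kfold(data, k=SELECTION_FOLDS, seed=seed)

    reg_selected = greedy_select(
        X, y, inner, "pearson",
        lambda: ExtraTreesRegressor(n_estimators=SELECTION_TREES,
                                    random_state=seed),
        max_features=MAX_SELECTED,
    )
    reg_report = evaluate_cv(
        X, y, lopo_folds(data),
        ModelConfig("regression", "extra_trees", seed),
        selected=reg_selected,
    )

    train_set, _test_set = split_by_position(
        data, test_fraction=BLIND_FRACTION, seed=seed
    )
    train_keys = {r.key for r in train_set.records}
    itr = [i for i, r in enumerate(data) if r.key in train_keys]
    ite = [i for i, r in enumerate(data) if r.key not in train_keys]
    est = make_model(ModelConfig("regression", "extra_trees", seed))
    est.fit(X.iloc[itr][reg_selected].to_numpy(), y[itr])
    blind_pred = est.predict(X.iloc[ite][reg_selected].to_numpy())
    blind_pearson = pearson(blind_pred, y[ite])

    yc = (y >= thr).astype(int)
    clf_selected = greedy_select(
        X, yc, inner, "mcc",
        lambda: RandomForestClassifier(n_estimators=SELECTION_TREES,
                                       random_state=seed,
                                       class_weight="balanced"),
        max_features=MAX_SELECTED,
    )
    clf_report = evaluate_cv(
        X, yc, lopo_folds(data.with_labels(thr)),
        ModelConfig("classification", "random_forest", seed),
        selected=clf_selected,
    )

    return {
        "lopo_pearson": reg_report.pooled["pearson"],
        "lopo_spearman": reg_report.pooled["spearman"],
        "lopo_kendall_tau": reg_report.pooled["kendall_tau"],
        "lopo_rmse": reg_report.pooled["rmse"],
        "lopo_pearson_trimmed": (reg_report.trimmed or {}).get("pearson"),
        "blind_pearson": blind_pearson,
        "classifier_mcc": clf_report.pooled["mcc"],
        "classifier_f1": clf_report.pooled["f1"],
        "classifier_bacc": clf_report.pooled["bacc"],
        "classifier_auc": clf_report.pooled["auc"],
        "n_records": len(data),
        "n_resistant": int(yc.sum()),
        "regressor_features": reg_selected,
        "classifier_features": clf_selected,
        "truth_features_recovered": sum(
            1 for s in reg_selected if s in truth["weights"]
        ),
    }


def planted_selection_hits(seed: int, n_repeats: int = 10) -> int:
    """How often greedy selection ranks a planted signal feature first.

    Each repeat plants one informative column among 20 pure-noise columns
    (y = signal + N(0, 0.05)) and runs one round of greedy selection under
    5-fold CV; returns the number of repeats whose first pick is the signal.
    """
    hits = 0
    for i in range(n_repeats):
        rng = np.random.default_rng(seed * 1000 + i)
        n = 80
        X = pd.DataFrame(
            rng.normal(size=(n, 20)),
            columns=[f"noise_{j:02d}" for j in range(20)],
        )
        X["signal"] = rng.normal(size=n)
        y = X["signal"].to_numpy() + rng.normal(scale=0.05, size=n)
        idx = rng.permutation(n)
        parts = np.array_split(idx, 5)
        folds = [
            (k,
             np.concatenate([p for j, p in enumerate(parts) if j != k]).tolist(),
             parts[k].tolist())
            for k in range(5)
        ]
        sel = greedy_select(
            X, y, folds, "pearson",
            lambda: ExtraTreesRegressor(n_estimators=20, random_state=seed),
            max_features=1,
        )
        hits += sel[0] == "signal"
    return hits
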