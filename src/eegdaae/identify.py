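"""Subject identification from latent features under a longitudinal protocol.

Feature tables hold one row per data cube (9 per trial): the aggregated
latent vector plus provenance columns. Every evaluation trains on
session-1 rows only and tests on session-2 rows only — the central
methodological guard against within-session leakage — and this split is
asserted on every scoring path.

Four classifier families are supported: KNN, ANN (multilayer perceptron),
SVM and Random Forest, each behind a standardizing pipeline. The headline
statistic is macro-averaged one-vs-rest AUC from class-probability
scores; pairwise identification accuracy matrices and per-subject
identifiability scores (row means of pairwise accuracies) mirror the
subject-separability analysis. Cross-validated model selection groups
folds by trial so cubes from one trial never straddle a fold boundary.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import ParameterGrid
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIER_KINDS",
    "CLASSIFIER_GRIDS",
    "feature_columns",
    "longitudinal_split",
    "make_classifier",
    "fit_and_score",
    "crossval_select",
    "pairwise_matrix",
    "identifiability",
    "drop_and_retrain",
    "write_report",
]

CLASSIFIER_KINDS = ("knn", "ann", "svm", "rf")

#: Declared search-space domains per classifier family.
CLASSIFIER_GRIDS: dict[str, dict[str, list]] = {
    "knn": {
        "n_neighbors": [3, 4, 5],
        "weights": ["uniform", "distance"],
        "algorithm": ["auto", "ball_tree", "kd_tree", "brute"],
        "leaf_size": [10, 15, 20, 25, 30, 35, 40, 45, 50],
        "metric": ["manhattan", "euclidean"],
    },
    # MLPClassifier offers relu/logistic (sigmoid); layer count 1-3
    "ann": {
        "hidden_layer_sizes": [(64,), (64, 32), (64, 32, 16)],
        "activation": ["relu", "logistic"],
        "solver": ["adam"],
    },
    "svm": {
        "kernel": ["linear", "rbf", "poly"],
        "gamma": ["scale", "auto"],
        "C": [0.1, 0.5, 1.0, 5.0, 10.0],  # log-spaced over [0.1, 10]
    },
    "rf": {
        "n_estimators": [100, 200, 300],
        "max_depth": [5, 10, 15],
        "min_samples_split": [2, 4, 6, 8, 10],
        "min_samples_leaf": [1, 2, 3, 4, 5],
        "max_features": ["sqrt", "log2"],
    },
}

_META_COLUMNS = ("subject", "session", "stimulus", "band", "scheme", "trial", "segment")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    return table[feature_columns(table)].to_numpy(), table["subject"].to_numpy()


def _assert_no_leakage(train: pd.DataFrame, test: pd.DataFrame) -> None:
    """Longitudinal guard: session-1 rows train, session-2 rows test, no overlap."""
    if not (train["session"] == 1).all():
        raise ValueError("leakage: training rows must all come from session 1")
    if not (test["session"] == 2).all():
        raise ValueError("leakage: test rows must all come from session 2")


def longitudinal_split(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train = session 1 only, test = session 2 only."""
    sessions = set(table["session"].unique())
    if not {1, 2} <= sessions:
        raise ValueError(f"both sessions required, table has {sorted(sessions)}")
    train = table[table["session"] == 1].reset_index(drop=True)
    test = table[table["session"] == 2].reset_index(drop=True)
    _assert_no_leakage(train, test)
    return train, test


def make_classifier(kind: str, params: dict | None = None, seed: int = 0) -> Pipeline:
    """Standardizing pipeline around the requested classifier family."""
    params = dict(params or {})
    if kind == "knn":
        clf = KNeighborsClassifier(**params)
    elif kind == "ann":
        params.setdefault("hidden_layer_sizes", (64,))
        params.setdefault("max_iter", 500)
        clf = MLPClassifier(random_state=seed, **params)
    elif kind == "svm":
        clf = SVC(probability=True, random_state=seed, **params)
    elif kind == "rf":
        clf = RandomForestClassifier(random_state=seed, **params)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; expected one of {CLASSIFIER_KINDS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _macro_ovr_auc(clf: Pipeline, X: np.ndarray, y: np.ndarray) -> float:
    classes = clf.classes_
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: test set contains a single class")
    proba = clf.predict_proba(X)
    if len(classes) == 2:
        return float(roc_auc_score(y, proba[:, 1]))
    return float(roc_auc_score(y, proba, multi_class="ovr", average="macro", labels=classes))


def fit_and_score(train: pd.DataFrame, test: pd.DataFrame, classifier_kind: str,
                  params: dict | None = None, seed: int = 0) -> float:
    """Fit on session-1 rows, return macro one-vs-rest AUC on session-2 rows."""
    _assert_no_leakage(train, test)
    clf = make_classifier(classifier_kind, params, seed)
    Xtr, ytr = _xy(train)
    Xte, yte = _xy(test)
    clf.fit(Xtr, ytr)
    return _macro_ovr_auc(clf, Xte, yte)


def _trial_folds(table: pd.DataFrame, k_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic fold row-indices, grouped by (subject, trial)."""
    groups = table[["subject", "trial"]].apply(tuple, axis=1).to_numpy()
    unique = sorted(set(groups))
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    assignment = {g: i % k_folds for i, g in enumerate(order)}
    fold_of_row = np.array([assignment[g] for g in groups])
    return [np.flatnonzero(fold_of_row == f) for f in range(k_folds)]


def crossval_select(train: pd.DataFrame, classifier_kind: str,
                    param_grid: dict[str, list] | None = None, k_folds: int = 5,
                    seed: int = 0, n_iter: int | None = None) -> dict:
    """Pick the grid point maximizing mean validation AUC over trial-grouped folds.

    ``n_iter`` subsamples the grid uniformly (seeded) instead of exhaustive
    enumeration; ties are broken by grid order, so the selection is
    deterministic given the seed.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    grid = list(ParameterGrid(param_grid if param_grid is not None
                              else CLASSIFIER_GRIDS[classifier_kind]))
    if not grid:
        raise ValueError("parameter grid is empty")
    if n_iter is not None and n_iter < len(grid):
        rng = np.random.default_rng(seed)
        grid = [grid[i] for i in sorted(rng.choice(len(grid), size=n_iter, replace=False))]

    folds = _trial_folds(train, k_folds, seed)
    X, y = _xy(train)
    best_params, best_score = None, -np.inf
    for params in grid:
        scores = []
        for f, val_idx in enumerate(folds):
            fit_idx = np.concatenate([folds[g] for g in range(k_folds) if g != f])
            clf = make_classifier(classifier_kind, params, seed)
            clf.fit(X[fit_idx], y[fit_idx])
            try:
                scores.append(_macro_ovr_auc(clf, X[val_idx], y[val_idx]))
            except ValueError:  # degenerate fold (single class)
                continue
        mean = float(np.mean(scores)) if scores else -np.inf
        if mean > best_score:
            best_params, best_score = params, mean
    return best_params


def pairwise_matrix(table: pd.DataFrame, classifier_kind: str,
                    params: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Binary longitudinal identification accuracy for every subject pair."""
    subjects = sorted(table["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("pairwise analysis needs >= 2 subjects")
    mat = pd.DataFrame(np.nan, index=subjects, columns=subjects)
    for a, b in itertools.combinations(subjects, 2):
        sub = table[table["subject"].isin([a, b])]
        train, test = longitudinal_split(sub)
        clf = make_classifier(classifier_kind, params, seed)
        Xtr, ytr = _xy(train)
        Xte, yte = _xy(test)
        clf.fit(Xtr, ytr)
        acc = float(accuracy_score(yte, clf.predict(Xte)))
        mat.loc[a, b] = acc
        mat.loc[b, a] = acc
    return mat


def identifiability(matrix: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Per-subject mean off-diagonal pairwise accuracy, plus the ascending ranking.

    Ties are broken lexicographically by subject id, so the least
    identifiable subjects are well-defined.
    """
    scores = matrix.mean(axis=1, skipna=True)
    ranked = sorted(scores.index, key=lambda s: (scores[s], s))
    return scores, ranked


def drop_and_retrain(table: pd.DataFrame, drop: list[str], classifier_kind: str,
                     params: dict | None = None, seed: int = 0) -> dict:
    """Re-run the longitudinal evaluation with ``drop`` subjects excluded."""
    subjects = set(table["subject"].unique())
    remaining = subjects - set(drop)
    if len(remaining) < 2:
        raise ValueError(
            f"dropping {sorted(drop)} leaves {len(remaining)} subject(s); need >= 2"
        )
    sub = table[table["subject"].isin(remaining)]
    train, test = longitudinal_split(sub)
    clf = make_classifier(classifier_kind, params, seed)
    Xtr, ytr = _xy(train)
    Xte, yte = _xy(test)
    clf.fit(Xtr, ytr)
    return {
        "n_subjects": len(remaining),
        "auc": _macro_ovr_auc(clf, Xte, yte),
        "accuracy": float(accuracy_score(yte, clf.predict(Xte))),
    }


def majority_vote_accuracy(train: pd.DataFrame, test: pd.DataFrame, classifier_kind: str,
                           params: dict | None = None, seed: int = 0) -> float:
    """Optional trial-level aggregation: majority vote over a trial's 9 cube votes."""
    _assert_no_leakage(train, test)
    clf = make_classifier(classifier_kind, params, seed)
    Xtr, ytr = _xy(train)
    clf.fit(Xtr, ytr)
    pred = pd.Series(clf.predict(test[feature_columns(test)].to_numpy()), index=test.index)
    votes = pred.groupby([test["subject"], test["trial"]]).agg(lambda s: s.mode().iloc[0])
    truth = votes.index.get_level_values(0)
    return float(accuracy_score(truth, votes.to_numpy()))


def write_report(report: dict, outdir: str | Path, matrices: dict[str, pd.DataFrame] | None = None,
                 heatmaps: bool = False) -> None:
    """Write an evaluation report as JSON (+ CSV matrices, optional PNG heatmaps)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    for name, mat in (matrices or {}).items():
        mat.to_csv(outdir / f"{name}.csv")
        if heatmaps:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.imshow(mat.to_numpy(dtype=float), vmin=0, vmax=1, cmap="viridis")
            ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90)
            ax.set_yticks(range(len(mat.index)), mat.index)
            fig.colorbar(im, ax=ax)
            fig.tight_layout()
            fig.savefig(outdir / f"{name}.png", dpi=120)
            plt.close(fig)
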