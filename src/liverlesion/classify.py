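"""ANOVA-F feature selection and extra-trees classification under LOPO.

The classifier is an extremely randomized trees ensemble: at every node a
random threshold is drawn for each feature of a random subset, and the best
of those random splits is kept. Settings follow the reference protocol:
700 trees, a minimum of five samples per leaf, ``round(sqrt(k))`` features
offered per node for ``k`` selected features (7 for k=50, 4 for k=19), and
per-sample class balancing (weights inversely proportional to the class
frequency in the training fold).

Evaluation is leave-one-patient-out (LOPO): every fold holds out *all*
lesions of one patient, and univariate ANOVA-F selection of the top
``n_selected`` features is recomputed on the training fold only, so no
information from the held-out lesions can leak into the selection.

The ablation harness compares four nested feature sets: A = T2-derived
features only, B = A + risk factors, C = all image features (T2 + DCE),
D = everything; with the top 19 features selected per fold (the size of
the smallest set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier

from .core import CLASS_ORDER
from .features import AREA_NAME, META_COLUMNS, RISK_NAMES

ABLATION_SETS = ("A", "B", "C", "D")


@dataclass
class ModelConfig:
    """Classifier and selection settings."""

    n_trees: int = 700
    min_samples_leaf: int = 5
    n_selected: int = 50
    seed: int = 0
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        if self.n_selected < 1:
            raise ValueError("n_selected must be at least 1")

    def features_per_node(self, n_selected: int | None = None) -> int:
        """round(sqrt(k)): 7 for the 50-feature model, 4 for the 19-feature one."""
        k = self.n_selected if n_selected is None else n_selected
        return max(1, int(round(np.sqrt(k))))


@dataclass
class FoldResult:
    """Outcome for one held-out lesion: truth, argmax prediction, probabilities."""

    lesion_id: str
    patient_id: str
    true_label: str
    predicted_label: str
    probabilities: np.ndarray  # aligned with CLASS_ORDER, sums to 1

    def probability(self, class_label: str) -> float:
        return float(self.probabilities[CLASS_ORDER.index(class_label)])


def anova_f(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per feature (column of ``X``).

    F = (between-group SS / (g-1)) / (within-group SS / (n-g)). A feature
    with zero within-group variance scores 0 if it is constant overall and
    +inf otherwise; both conventions keep top-k selection well defined.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.unique(y)
    if groups.size < 2:
        raise ValueError("ANOVA needs at least 2 classes")
    n, _ = X.shape
    grand_mean = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for g in groups:
        block = X[y == g]
        gm = block.mean(axis=0)
        ss_between += block.shape[0] * (gm - grand_mean) ** 2
        ss_within += ((block - gm) ** 2).sum(axis=0)
    df1 = groups.size - 1
    df2 = n - groups.size
    if df2 <= 0:
        raise ValueError("ANOVA needs more samples than classes")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    f[ss_within == 0] = np.where(ss_between[ss_within == 0] <= 1e-30, 0.0, np.inf)
    return np.nan_to_num(f, nan=0.0, posinf=np.inf)


def select_top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``k`` largest scores; ties broken toward the lower index."""
    scores = np.asarray(scores, dtype=float)
    if k > scores.size:
        raise ValueError(f"cannot select {k} of {scores.size} features")
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:k])


def _balanced_sample_weights(y: np.ndarray) -> np.ndarray:
    """Weights inversely proportional to the class frequency in ``y``."""
    classes, counts = np.unique(y, return_counts=True)
    freq = dict(zip(classes, counts))
    return np.array([len(y) / (len(classes) * freq[label]) for label in y])


def fit_extra_trees(
    X: np.ndarray, y: np.ndarray, config: ModelConfig, n_selected: int | None = None
) -> ExtraTreesClassifier:
    """Fit the extra-trees ensemble with class-balanced sample weights."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.size == 0:
        raise ValueError("empty training matrix")
    model = ExtraTreesClassifier(
        n_estimators=config.n_trees,
        min_samples_leaf=config.min_samples_leaf,
        max_features=config.features_per_node(n_selected if n_selected else X.shape[1]),
        random_state=config.seed,
    )
    model.fit(X, y, sample_weight=_balanced_sample_weights(y))
    return model


def _feature_matrix(table: pd.DataFrame, feature_names: list[str]) -> np.ndarray:
    return table[feature_names].to_numpy(dtype=float)


def lopo_crossval(
    table: pd.DataFrame,
    config: ModelConfig | None = None,
    feature_names: list[str] | None = None,
) -> list[FoldResult]:
    """Leave-one-patient-out cross-validation with in-fold feature selection.

    ``table`` is a feature table (one row per lesion, ``patient_id``,
    ``lesion_id``, ``label`` plus feature columns). Returns one
    :class:`FoldResult` per lesion. Folds whose training part lost a whole
    class are skipped with a warning (only possible on tiny cohorts).
    """
    if config is None:
        config = ModelConfig()
    if feature_names is None:
        feature_names = [c for c in table.columns if c not in META_COLUMNS]
    patients = sorted(table["patient_id"].unique())
    if len(patients) < 2:
        raise ValueError("LOPO needs at least 2 patients")
    k = min(config.n_selected, len(feature_names))

    results: list[FoldResult] = []
    for fold_index, patient in enumerate(patients):
        test = table[table["patient_id"] == patient]
        train = table[table["patient_id"] != patient]
        if set(train["label"].unique()) != set(table["label"].unique()):
            warnings.warn(
                f"fold for patient {patient} skipped: a class is absent from training",
                stacklevel=2,
            )
            continue
        X_train = _feature_matrix(train, feature_names)
        y_train = train["label"].to_numpy()
        scores = anova_f(X_train, y_train)
        selected = select_top_k(scores, k)
        fold_config = ModelConfig(
            n_trees=config.n_trees,
            min_samples_leaf=config.min_samples_leaf,
            n_selected=config.n_selected,
            seed=config.seed + fold_index,
            class_order=config.class_order,
        )
        model = fit_extra_trees(X_train[:, selected], y_train, fold_config, n_selected=k)
        X_test = _feature_matrix(test, feature_names)[:, selected]
        proba = model.predict_proba(X_test)
        class_to_col = {c: i for i, c in enumerate(model.classes_)}
        for row_idx, (_, row) in enumerate(test.iterrows()):
            p = np.zeros(len(CLASS_ORDER))
            for c, col in class_to_col.items():
                p[CLASS_ORDER.index(c)] = proba[row_idx, col]
            predicted = CLASS_ORDER[int(np.argmax(p))]
            results.append(
                FoldResult(
                    lesion_id=str(row["lesion_id"]),
                    patient_id=str(row["patient_id"]),
                    true_label=str(row["label"]),
                    predicted_label=predicted,
                    probabilities=p,
                )
            )
    return results


def ablation_feature_sets(all_feature_names: list[str]) -> dict[str, list[str]]:
    """The four nested feature sets A-D of the ablation experiment."""
    t2 = [n for n in all_feature_names if n.startswith(("hist.t2.", "glcm.t2."))]
    risk = [n for n in all_feature_names if n in RISK_NAMES]
    image = [n for n in all_feature_names if n not in RISK_NAMES and n != AREA_NAME]
    return {"A": t2, "B": t2 + risk, "C": image, "D": list(all_feature_names)}


def run_ablation(
    table: pd.DataFrame,
    config: ModelConfig | None = None,
    n_selected: int = 19,
) -> dict[str, list[FoldResult]]:
    """LOPO results for feature sets A-D with top-``n_selected`` in-fold selection."""
    if config is None:
        config = ModelConfig()
    feature_names = [c for c in table.columns if c not in META_COLUMNS]
    sets = ablation_feature_sets(feature_names)
    out = {}
    for name in ABLATION_SETS:
        cfg = ModelConfig(
            n_trees=config.n_trees,
            min_samples_leaf=config.min_samples_leaf,
            n_selected=min(n_selected, len(sets[name])),
            seed=config.seed,
            class_order=config.class_order,
        )
        out[name] = lopo_crossval(table, cfg, feature_names=sets[name])
    return out


def tune_grid(
    table: pd.DataFrame,
    feature_counts: list[int] | None = None,
    tree_counts: list[int] | None = None,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """LOPO accuracy over a grid of (n_selected, n_trees) settings.

    Defaults reproduce the reference search: features 10..164 in steps of
    10 and trees 100..800 in steps of 50. The grid is expensive; callers
    normally pass a reduced grid.
    """
    if config is None:
        config = ModelConfig()
    n_features = len([c for c in table.columns if c not in META_COLUMNS])
    if feature_counts is None:
        feature_counts = [k for k in range(10, 165, 10) if k <= n_features]
    if tree_counts is None:
        tree_counts = list(range(100, 801, 50))
    rows = []
    for k in feature_counts:
        for n_trees in tree_counts:
            cfg = ModelConfig(
                n_trees=n_trees,
                min_samples_leaf=config.min_samples_leaf,
                n_selected=k,
                seed=config.seed,
            )
            folds = lopo_crossval(table, cfg)
            accuracy = float(
                np.mean([f.true_label == f.predicted_label for f in folds])
            )
            rows.append({"n_selected": k, "n_trees": n_trees, "accuracy": accuracy})
    return pd.DataFrame(rows)
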