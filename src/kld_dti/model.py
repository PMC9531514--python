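"""KLD feature assembly and the random-forest DTI classifier.

Each query ligand is described by a K-dimensional vector of generalized
KL divergences: its Q-L similarity density against each of the K target
Q-Q densities.  A small divergence in column k means the query "looks
like" target k's ligands from that target's own point of view, so a
multi-class random forest over the K columns learns the target assignment
without any similarity cutoff.

Feature construction excludes a training ligand's own conformers from the
class side of its own-class Q-L vector by default (``exclude_self``):
leaving them in plants unit similarities that leak the label.

Out-of-set targets are supported in both directions: a query may carry a
label with no Q-Q density (it contributes rows but no feature column),
and a class too small to estimate a density is simply dropped from the
feature columns while its ligands remain in the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    train_test_split,
)

from .density import DensityProfile, estimate_density
from .divergence import DEFAULT_EPSILON, generalized_kld
from .errors import ConfigurationError, InputError
from .fpset import FingerprintCollection
from .similarity import DEFAULT_CAP, QQMatrix, build_ql_vector, build_qq_matrix

logger = logging.getLogger(__name__)

FEATURE_PREFIX = "KLD_"
LABEL_COLUMN = "label"


@dataclass
class TargetModel:
    """One target class's capped conformer set, Q-Q scores and density."""

    qq: QQMatrix
    profile: DensityProfile


def fit_target_models(
    collection: FingerprintCollection,
    cap: int = DEFAULT_CAP,
    seed: int = 0,
    bandwidth_rule: str = "scott",
    renormalize: bool = True,
    min_conformers: int = 2,
) -> dict[str, TargetModel]:
    """Build the Q-Q matrix and density profile for every target class.

    Classes with fewer than ``min_conformers`` fingerprints cannot support
    a density and are skipped with a warning; their ligands can still be
    featurized against the remaining targets (the out-of-set scenario).
    """
    models: dict[str, TargetModel] = {}
    for class_id in collection.class_ids:
        class_fps = collection.for_class(class_id)
        if len(class_fps) < min_conformers:
            logger.warning(
                "class %s has %d fingerprint(s); no Q-Q density built",
                class_id,
                len(class_fps),
            )
            continue
        qq = build_qq_matrix(class_fps, cap=cap, seed=seed)
        profile = estimate_density(
            qq.values, bandwidth_rule=bandwidth_rule, renormalize=renormalize
        )
        models[class_id] = TargetModel(qq=qq, profile=profile)
    if len(models) < 2:
        raise InputError(
            f"only {len(models)} class(es) support a density; need >= 2"
        )
    return models


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith(FEATURE_PREFIX)]


def build_feature_table(
    collection: FingerprintCollection,
    target_models: dict[str, TargetModel],
    exclude_self: bool = True,
    epsilon: float = DEFAULT_EPSILON,
    bandwidth_rule: str = "scott",
    renormalize: bool = True,
) -> pd.DataFrame:
    """Per-query KLD feature vectors.

    For each query ligand and each of the K modeled targets: pool the Q-L
    similarities, estimate their density p(x), and compute
    KL(p | q_target).  Columns are ordered by target label; the true label
    rides along in the ``label`` column (it may name a target without a
    feature column).  Queries whose Q-L vector cannot support a density
    for some target are skipped with a logged reason.
    """
    targets = sorted(target_models)
    rows, labels, index = [], [], []
    for ligand_id, class_id, query_packed in collection.iter_ligands():
        feats = np.empty(len(targets))
        try:
            for k, tgt in enumerate(targets):
                tm = target_models[tgt]
                ql = build_ql_vector(
                    query_packed,
                    tm.qq,
                    exclude_self=exclude_self and class_id == tgt,
                    query_id=ligand_id,
                )
                p = estimate_density(
                    ql.values,
                    bandwidth_rule=bandwidth_rule,
                    renormalize=renormalize,
                )
                feats[k] = generalized_kld(
                    p, tm.profile, epsilon=epsilon,
                    p_source=f"QL:{ligand_id}|{tgt}", q_source=f"QQ:{tgt}",
                ).value
        except InputError as exc:
            logger.warning("skipping query %s: %s", ligand_id, exc)
            continue
        rows.append(feats)
        labels.append(class_id)
        index.append(ligand_id)
    if not rows:
        raise InputError("no query could be featurized")
    table = pd.DataFrame(
        rows, columns=[FEATURE_PREFIX + t for t in targets], index=index
    )
    table[LABEL_COLUMN] = labels
    table.index.name = "ligand_id"
    return table


def split_train_test(
    table: pd.DataFrame,
    test_fraction: float = 0.25,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 75/25 (by default) train/test split, reproducible per seed."""
    if not 0.0 < test_fraction < 1.0:
        raise ConfigurationError("test_fraction must be in (0, 1)")
    counts = table[LABEL_COLUMN].value_counts()
    singletons = counts[counts < 2]
    if stratified and not singletons.empty:
        raise InputError(
            f"classes with a single row cannot be split: "
            f"{list(singletons.index)}"
        )
    train, test = train_test_split(
        table,
        test_size=test_fraction,
        stratify=table[LABEL_COLUMN] if stratified else None,
        random_state=seed,
    )
    return train, test


def train_rf(
    train: pd.DataFrame,
    n_estimators: int = 500,
    seed: int = 0,
    tune: bool = False,
    **forest_kwargs,
) -> RandomForestClassifier:
    """Fit the multi-class random forest on KLD features.

    ``tune=True`` runs a small grid search over depth/feature sub-sampling
    (mirroring automatic hyperparameter adjustment); by default the forest
    uses 500 trees with impurity-based splitting defaults and records an
    out-of-bag score.
    """
    X = train[feature_columns(train)].to_numpy()
    y = train[LABEL_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        raise InputError("training data contains a single class")
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
        **forest_kwargs,
    )
    if tune:
        grid = GridSearchCV(
            RandomForestClassifier(
                n_estimators=n_estimators, oob_score=True, random_state=seed,
                n_jobs=1,
            ),
            param_grid={
                "max_depth": [None, 8, 16],
                "max_features": ["sqrt", None],
            },
            cv=3,
        )
        grid.fit(X, y)
        rf = grid.best_estimator_
    else:
        rf.fit(X, y)
    return rf


def cross_validate(
    table: pd.DataFrame, folds: int = 5, seed: int = 0, n_estimators: int = 500
) -> tuple[np.ndarray, float]:
    """Stratified k-fold accuracies and their mean."""
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    counts = table[LABEL_COLUMN].value_counts()
    if (counts < folds).any():
        raise InputError(
            f"classes smaller than {folds} folds: "
            f"{list(counts[counts < folds].index)}"
        )
    X = table[feature_columns(table)].to_numpy()
    y = table[LABEL_COLUMN].to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        rf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        )
        rf.fit(X[train_idx], y[train_idx])
        accs.append(rf.score(X[test_idx], y[test_idx]))
    accs = np.asarray(accs)
    return accs, float(accs.mean())


@dataclass
class EvaluationReport:
    """Held-out performance of a trained DTI classifier."""

    labels: list[str]
    precision: pd.Series
    recall: pd.Series
    f1: pd.Series
    support: pd.Series
    accuracy: float
    confusion: pd.DataFrame
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]] = field(repr=False)
    auc: pd.Series = field(repr=False)
    oob_score: float | None = None
    n_out_of_set: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
                "auc": self.auc,
            }
        )


def evaluate(
    model: RandomForestClassifier,
    test: pd.DataFrame,
    out_of_set_labels: tuple[str, ...] = (),
) -> EvaluationReport:
    """Score a trained forest on held-out rows.

    Rows whose true label the model never saw are an error unless the
    label is registered in ``out_of_set_labels``; registered rows count
    against overall accuracy (the model cannot predict them) but are
    excluded from per-class metrics and ROC.
    """
    if test.empty:
        raise InputError("test set is empty")
    known = list(model.classes_)
    unseen = set(test[LABEL_COLUMN]) - set(known) - set(out_of_set_labels)
    if unseen:
        raise InputError(
            f"test labels unknown to the model: {sorted(unseen)}; "
            "register them as out-of-set to proceed"
        )
    oos_mask = test[LABEL_COLUMN].isin(out_of_set_labels).to_numpy()
    in_set = test.loc[~oos_mask]
    X = in_set[feature_columns(in_set)].to_numpy()
    y = in_set[LABEL_COLUMN].to_numpy()
    y_pred = model.predict(X)
    y_proba = model.predict_proba(X)

    prec, rec, f1, support = precision_recall_fscore_support(
        y, y_pred, labels=known, zero_division=0
    )
    conf = confusion_matrix(y, y_pred, labels=known)
    roc_curves, aucs = {}, {}
    for k, lbl in enumerate(known):
        y_bin = (y == lbl).astype(int)
        if y_bin.min() == y_bin.max():  # class absent (or alone) in test
            aucs[lbl] = np.nan
            continue
        fpr, tpr, _ = roc_curve(y_bin, y_proba[:, k])
        roc_curves[lbl] = (fpr, tpr)
        aucs[lbl] = roc_auc_score(y_bin, y_proba[:, k])

    n_oos = int(oos_mask.sum())
    accuracy = float((y_pred == y).sum()) / len(test)
    return EvaluationReport(
        labels=known,
        precision=pd.Series(prec, index=known),
        recall=pd.Series(rec, index=known),
        f1=pd.Series(f1, index=known),
        support=pd.Series(support, index=known),
        accuracy=accuracy,
        confusion=pd.DataFrame(conf, index=known, columns=known),
        roc_curves=roc_curves,
        auc=pd.Series(aucs),
        oob_score=getattr(model, "oob_score_", None),
        n_out_of_set=n_oos,
    )


@dataclass
class FeatureAnalysis:
    """Correlation, importance and pruning diagnostics for the KLD features."""

    correlation: pd.DataFrame
    importances: pd.Series
    pruning: pd.DataFrame  # columns: n_features, accuracy, oob_score


def feature_analysis(
    model: RandomForestClassifier,
    table: pd.DataFrame,
    seed: int = 0,
    test_fraction: float = 0.25,
) -> FeatureAnalysis:
    """Pearson feature correlations, impurity importances, pruning curve.

    The pruning curve retrains the forest on the top-m features (ranked by
    mean decrease in impurity, ties broken by column order) for
    m = 1..K and records held-out accuracy and OOB score for each m.
    """
    cols = feature_columns(table)
    if len(cols) < 2:
        raise InputError("need >= 2 features for analysis")
    X = table[cols]
    # constant columns yield undefined correlations; pandas reports NaN there
    correlation = X.corr(method="pearson")
    importances = pd.Series(model.feature_importances_, index=cols)
    # stable ranking: descending importance, ties by column order
    order = sorted(range(len(cols)), key=lambda i: (-importances.iloc[i], i))

    train, test = split_train_test(
        table, test_fraction=test_fraction, stratified=True, seed=seed
    )
    records = []
    for m in range(1, len(cols) + 1):
        keep = [cols[i] for i in order[:m]]
        sub_train = train[keep + [LABEL_COLUMN]]
        rf = train_rf(sub_train, n_estimators=model.n_estimators, seed=seed)
        acc = rf.score(test[keep].to_numpy(), test[LABEL_COLUMN].to_numpy())
        records.append(
            {"n_features": m, "accuracy": acc, "oob_score": rf.oob_score_}
        )
    return FeatureAnalysis(
        correlation=correlation,
        importances=importances,
        pruning=pd.DataFrame(records),
    )
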